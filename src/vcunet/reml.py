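"""REML estimation for the trial-network mixed models.

The engine assembles Henderson's mixed-model equations (MME)

    C = [[X'R^-1 X, X'R^-1 Z], [Z'R^-1 X, Z'R^-1 Z + G^-1]]

and evaluates the restricted log-likelihood through the identity

    -2 l_R = log|R| + log|G| + log|C| + y'Py + (n - p) log 2*pi,

maximizing it over log-variances and atanh-correlations with a
quasi-Newton search (optionally polished by a derivative-free simplex for
small problems).  Because every record loads on only a handful of effect
levels, C is sparse; a sparse LU factorization supplies both log|C| and
solves, and the same factorization at the optimum gives BLUPs, fixed-effect
standard errors, and any block of the generalized inverse of C — the
quantity behind prediction error variances of BLUP differences and
pairwise SEDs.

Any subset of variances/correlations can be frozen at given values, which
serves both the zero-correlation counterfactual in network merging and
likelihood-ratio tests of single correlations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import chi2, norm

from .data import METDataset, logit
from .model import FixedTerm, ModelSpec, RandomTerm

_LOG2PI = float(np.log(2.0 * np.pi))
_BIG = 1.0e12


class AliasingError(ValueError):
    """The fixed-effects design is rank deficient."""


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def prepare_frame(
    dataset: METDataset,
    *,
    registration_years: dict[str, int] | None = None,
    zero_r: bool = False,
) -> pd.DataFrame:
    """Augment the records with model covariates.

    ``_t`` is the trial year scaled so the reference year is 0; ``_r`` is
    the variety's first year of appearance on the same scale (or its
    registration year when a map is supplied, supporting the sensitivity
    analysis of trend estimates).  ``year_f`` is the year as a categorical
    label, distinct from the numeric trend covariate.
    """
    df = dataset.records.copy()
    ref = dataset.reference_year
    df["_t"] = (df["year"] - ref).astype(float)
    if zero_r:
        df["_r"] = 0.0
    elif registration_years is not None:
        missing = set(df["variety"]) - set(registration_years)
        if missing:
            raise ValueError(f"no registration year for: {sorted(missing)[:5]}")
        df["_r"] = df["variety"].map(registration_years).astype(float) - ref
    else:
        df["_r"] = df["variety"].map(dataset.fyoa).astype(float) - ref
    df["year_f"] = df["year"].astype(str)
    df = df[np.isfinite(df["value"])].reset_index(drop=True)
    return df


def response_vector(df: pd.DataFrame) -> np.ndarray:
    """Trait values on the analysis scale (logit for protein content)."""
    y = df["value"].to_numpy(dtype=float).copy()
    mask = (df["trait"] == "protein_content").to_numpy()
    if mask.any():
        y[mask] = logit(y[mask])
    return y


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _labels(df: pd.DataFrame, factors, allow_empty: bool = False) -> pd.Series:
    """Interaction labels 'a:b:c'; empty-string factor values yield None.

    Rows with an empty factor value do not load on the term (e.g. records
    without subtrials carry no subtrial effect); the residual is the
    exception (``allow_empty``), since every record has a residual.
    """
    s = df[factors[0]].astype(str)
    valid = df[factors[0]].astype(str) != ""
    for f in factors[1:]:
        col = df[f].astype(str)
        s = s + ":" + col
        valid &= col != ""
    if allow_empty:
        return s
    return s.where(valid, None)


def build_fixed_matrix(df: pd.DataFrame, terms: list[FixedTerm]):
    cols, names = [], []
    for t in terms:
        cov = df[t.covariate].to_numpy(float) if t.covariate else None
        if not t.factors:
            cols.append(cov if cov is not None else np.ones(len(df)))
            names.append(t.name)
            continue
        lab = _labels(df, t.factors)
        levels = sorted(lab.dropna().unique())
        if t.covariate is None and t.coding == "drop_first":
            if t.within is not None:
                w = df[t.within].astype(str)
                drop = {
                    min(l for l in levels if l.startswith(g + ":"))
                    for g in sorted(w.unique())
                }
                levels = [l for l in levels if l not in drop]
            else:
                levels = levels[1:]
        for lev in levels:
            d = (lab == lev).to_numpy(float)
            if cov is not None:
                d = d * cov
            cols.append(d)
            names.append(f"{t.name}[{lev}]" if t.factors else t.name)
    X = np.column_stack(cols)
    # rank check with names of aliased columns
    r = np.linalg.matrix_rank(X.T @ X)
    if r < X.shape[1]:
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        keep = np.abs(np.diag(R)) > 1e-8 * np.abs(R[0, 0])
        aliased = [names[piv[i]] for i in range(len(names)) if not keep[i]]
        raise AliasingError(f"aliased fixed-effect columns: {aliased}")
    return X, names


@dataclasses.dataclass
class _TermBlock:
    term: RandomTerm
    col_slice: slice  # within Z
    labels: list[str]  # column labels
    groups: list[str]  # structure groups (len 1 for sci)
    group_of_col: np.ndarray | None  # for group_diag: group index per column
    n_base: int  # for us2: number of base levels (columns = 2 * n_base)


def build_random_matrix(df: pd.DataFrame, terms: list[RandomTerm]):
    """Sparse Z plus per-term column metadata.

    For ``us2`` terms, columns are ordered [all base levels x group 1,
    all base levels x group 2]; base levels never observed in one group
    still get a (zero) column there so their effects remain predictable.
    """
    n = len(df)
    blocks: list[_TermBlock] = []
    rows_all, cols_all = [], []
    offset = 0
    for t in terms:
        if t.structure == "us2":
            base = _labels(df, t.factors)
            grp = df[t.group].astype(str)
            valid = base.notna().to_numpy()
            base_levels = sorted(base.dropna().unique())
            groups = sorted(grp.unique())
            if len(groups) != 2:
                raise ValueError(f"{t.name}: us2 needs exactly 2 groups, got {groups}")
            bindex = {b: i for i, b in enumerate(base_levels)}
            gindex = {g: i for i, g in enumerate(groups)}
            m = len(base_levels)
            bvals, gvals = base.to_numpy(), grp.to_numpy()
            rr = np.where(valid)[0]
            cc = np.array(
                [offset + gindex[gvals[i]] * m + bindex[bvals[i]] for i in rr],
                dtype=int,
            )
            labels = [f"{t.name}[{g}:{b}]" for g in groups for b in base_levels]
            blocks.append(
                _TermBlock(t, slice(offset, offset + 2 * m), labels, groups, None, m)
            )
            offset += 2 * m
        else:
            lab = _labels(df, t.factors)
            valid = lab.notna().to_numpy()
            levels = sorted(lab.dropna().unique())
            lindex = {l: i for i, l in enumerate(levels)}
            lvals = lab.to_numpy()
            rr = np.where(valid)[0]
            cc = np.array([offset + lindex[lvals[i]] for i in rr], dtype=int)
            labels = [f"{t.name}[{l}]" for l in levels]
            if t.structure == "group_diag":
                gpos = t.factors.index(t.group)
                lev_groups = [l.split(":")[gpos] for l in levels]
                groups = sorted(set(lev_groups))
                gidx = {g: i for i, g in enumerate(groups)}
                group_of_col = np.array([gidx[g] for g in lev_groups], dtype=int)
            else:
                groups = ["*"]
                group_of_col = None
            blocks.append(
                _TermBlock(
                    t, slice(offset, offset + len(levels)), labels, groups,
                    group_of_col, len(levels),
                )
            )
            offset += len(levels)
        rows_all.append(rr)
        cols_all.append(cc)
    if offset == 0:
        return sp.csc_matrix((n, 0)), blocks
    Z = sp.csc_matrix(
        (
            np.ones(sum(len(r) for r in rows_all)),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(n, offset),
    )
    return Z, blocks


# ---------------------------------------------------------------------------
# Variance parameters
# ---------------------------------------------------------------------------

def param_names(term: RandomTerm, groups: list[str]) -> list[str]:
    """Natural-scale parameter names for one random term."""
    if term.structure == "sci":
        return [f"sigma2_{term.name}"]
    if term.structure == "group_diag":
        return [f"sigma2_{term.name}:{g}" for g in groups]
    return [f"sigma2_{term.name}:{g}" for g in groups] + [f"rho_{term.name}"]


@dataclasses.dataclass
class _Param:
    name: str
    kind: str  # "var" | "rho"
    term: str


class VarianceComponents(dict):
    """Mapping parameter name -> value on the natural scale.

    Variances are named ``sigma2_<term>`` (or ``sigma2_<term>:<group>``)
    and correlations ``rho_<term>``.
    """

    def variance(self, term: str, group: str | None = None) -> float:
        key = f"sigma2_{term}" if group is None else f"sigma2_{term}:{group}"
        return float(self[key])

    def rho(self, term: str) -> float:
        return float(self[f"rho_{term}"])


# ---------------------------------------------------------------------------
# Residual (R matrix) handling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _ResidMeta:
    structure: str
    groups: list[str]
    group_rows: list[np.ndarray]  # for sci/group_diag: row indices per group
    pair_rows: tuple[np.ndarray, np.ndarray] | None  # aligned us2 pairs
    unpaired_rows: list[np.ndarray] | None  # per-group leftovers for us2


def _residual_meta(df: pd.DataFrame, term: RandomTerm) -> _ResidMeta:
    if term.structure == "us2":
        base = _labels(df, term.factors, allow_empty=True)
        grp = df[term.group].astype(str)
        groups = sorted(grp.unique())
        if len(groups) != 2:
            raise ValueError("us2 residual needs exactly 2 groups")
        g1 = df.index[(grp == groups[0])].to_numpy()
        g2 = df.index[(grp == groups[1])].to_numpy()
        key1 = {base[i]: i for i in g1}
        key2 = {base[i]: i for i in g2}
        common = sorted(set(key1) & set(key2))
        p1 = np.array([key1[k] for k in common], dtype=int)
        p2 = np.array([key2[k] for k in common], dtype=int)
        u1 = np.array(sorted(set(g1) - set(p1)), dtype=int)
        u2 = np.array(sorted(set(g2) - set(p2)), dtype=int)
        return _ResidMeta("us2", groups, [], (p1, p2), [u1, u2])
    if term.structure == "group_diag":
        gpos = term.group
        grp = df[gpos].astype(str)
        groups = sorted(grp.unique())
        rows = [df.index[grp == g].to_numpy() for g in groups]
        return _ResidMeta("group_diag", groups, rows, None, None)
    return _ResidMeta("sci", ["*"], [np.arange(len(df))], None, None)


# ---------------------------------------------------------------------------
# The MME problem
# ---------------------------------------------------------------------------

class MMEProblem:
    """Precomputed design pieces + restricted-likelihood evaluation."""

    def __init__(self, y: np.ndarray, X: np.ndarray, x_names, Z, blocks, rmeta):
        self.y = y
        self.X = X
        self.x_names = list(x_names)
        self.Z = Z
        self.blocks = blocks
        self.rmeta = rmeta
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.dim = self.p + self.q
        W = sp.hstack([sp.csc_matrix(X), Z], format="csr")
        self.W = W
        self.col_labels = list(x_names) + [l for b in blocks for l in b.labels]
        # per-residual-piece Gram matrices
        self._grams, self._rhs, self._yy, self._nrows = [], [], [], []
        if rmeta.structure == "us2":
            p1, p2 = rmeta.pair_rows
            W1, W2 = W[p1], W[p2]
            y1, y2 = y[p1], y[p2]
            self._pair = (
                (W1.T @ W1).tocsc(), (W2.T @ W2).tocsc(),
                (W1.T @ W2).tocsc(),
                W1.T @ y1, W2.T @ y2, W1.T @ y2, W2.T @ y1,
                float(y1 @ y1), float(y2 @ y2), float(y1 @ y2), len(p1),
            )
            for rows in rmeta.unpaired_rows:
                Wg, yg = W[rows], y[rows]
                self._grams.append((Wg.T @ Wg).tocsc())
                self._rhs.append(Wg.T @ yg)
                self._yy.append(float(yg @ yg))
                self._nrows.append(len(rows))
        else:
            self._pair = None
            for rows in rmeta.group_rows:
                Wg, yg = W[rows], y[rows]
                self._grams.append((Wg.T @ Wg).tocsc())
                self._rhs.append(Wg.T @ yg)
                self._yy.append(float(yg @ yg))
                self._nrows.append(len(rows))
        # parameter list
        self.params: list[_Param] = []
        for b in blocks + ["resid"]:
            if b == "resid":
                term, groups = None, rmeta.groups
                names = param_names(
                    RandomTerm("GLY'", ("x",)) if rmeta.structure == "sci"
                    else RandomTerm("GLY'", ("x",), "group_diag", "x")
                    if rmeta.structure == "group_diag"
                    else RandomTerm("GLY'", ("x",), "us2", "g"),
                    groups,
                )
                tname = "GLY'"
            else:
                names = param_names(b.term, b.groups)
                tname = b.term.name
            for nm in names:
                self.params.append(
                    _Param(nm, "rho" if nm.startswith("rho_") else "var", tname)
                )
        self.param_names = [p.name for p in self.params]
        self._setup_absorption()

    # -- assembly ----------------------------------------------------------

    def _r_pieces(self, vc: VarianceComponents):
        """Coefficients assembling W'R^-1 W, W'R^-1 y, y'R^-1 y, log|R|."""
        rm = self.rmeta
        A = sp.csc_matrix((self.dim, self.dim))
        rhs = np.zeros(self.dim)
        yy = 0.0
        logdetR = 0.0
        if rm.structure == "us2":
            v1 = vc[f"sigma2_GLY':{rm.groups[0]}"]
            v2 = vc[f"sigma2_GLY':{rm.groups[1]}"]
            r = vc["rho_GLY'"]
            det = v1 * v2 * (1.0 - r * r)
            if det <= 0 or v1 <= 0 or v2 <= 0:
                return None
            a = v2 / det
            c = v1 / det
            b = -r * np.sqrt(v1 * v2) / det
            G11, G22, G12, h1, h2, h12, h21, yy1, yy2, yy12, npair = self._pair
            A = a * G11 + c * G22 + b * (G12 + G12.T)
            rhs = a * h1 + c * h2 + b * (h12 + h21)
            yy = a * yy1 + c * yy2 + 2.0 * b * yy12
            logdetR += npair * np.log(det)
            for g, (Gg, hg, yyg, ng) in enumerate(
                zip(self._grams, self._rhs, self._yy, self._nrows)
            ):
                vg = (v1, v2)[g]
                if ng:
                    A = A + Gg / vg
                    rhs = rhs + hg / vg
                    yy += yyg / vg
                    logdetR += ng * np.log(vg)
        else:
            for g, grp in enumerate(rm.groups):
                key = "sigma2_GLY'" if rm.structure == "sci" else f"sigma2_GLY':{grp}"
                vg = vc[key]
                if vg <= 0:
                    return None
                A = A + self._grams[g] / vg
                rhs = rhs + self._rhs[g] / vg
                yy += self._yy[g] / vg
                logdetR += self._nrows[g] * np.log(vg)
        return A.tocsc(), rhs, yy, logdetR

    def _r_coefs(self, vc: VarianceComponents):
        """Per-group Gram coefficients (diagonal-residual structures only)."""
        rm = self.rmeta
        coefs, rhs, yy, logdetR = [], np.zeros(self.dim), 0.0, 0.0
        for g, grp in enumerate(rm.groups):
            key = "sigma2_GLY'" if rm.structure == "sci" else f"sigma2_GLY':{grp}"
            vg = vc[key]
            if vg <= 0:
                return None
            coefs.append(1.0 / vg)
            rhs = rhs + self._rhs[g] / vg
            yy += self._yy[g] / vg
            logdetR += self._nrows[g] * np.log(vg)
        return coefs, rhs, yy, logdetR

    def _ginv(self, vc: VarianceComponents):
        """Sparse G^-1 (over Z columns) and log|G|."""
        rows, cols, vals = [], [], []
        logdetG = 0.0
        for blk in self.blocks:
            t = blk.term
            off = blk.col_slice.start + self.p
            if t.structure == "sci":
                v = vc[f"sigma2_{t.name}"]
                if v <= 0:
                    return None
                idx = np.arange(off, off + blk.n_base)
                rows.append(idx)
                cols.append(idx)
                vals.append(np.full(blk.n_base, 1.0 / v))
                logdetG += blk.n_base * np.log(v)
            elif t.structure == "group_diag":
                vgs = np.array([vc[f"sigma2_{t.name}:{g}"] for g in blk.groups])
                if np.any(vgs <= 0):
                    return None
                per_col = vgs[blk.group_of_col]
                idx = np.arange(off, off + blk.n_base)
                rows.append(idx)
                cols.append(idx)
                vals.append(1.0 / per_col)
                logdetG += float(np.sum(np.log(per_col)))
            else:  # us2
                v1 = vc[f"sigma2_{t.name}:{blk.groups[0]}"]
                v2 = vc[f"sigma2_{t.name}:{blk.groups[1]}"]
                r = vc[f"rho_{t.name}"]
                det = v1 * v2 * (1.0 - r * r)
                if det <= 0 or v1 <= 0 or v2 <= 0:
                    return None
                a = v2 / det
                c = v1 / det
                b = -r * np.sqrt(v1 * v2) / det
                m = blk.n_base
                i1 = np.arange(off, off + m)
                i2 = np.arange(off + m, off + 2 * m)
                rows += [i1, i2, i1, i2]
                cols += [i1, i2, i2, i1]
                vals += [np.full(m, a), np.full(m, c), np.full(m, b), np.full(m, b)]
                logdetG += m * np.log(det)
        if not rows:
            return sp.csc_matrix((self.dim, self.dim)), 0.0
        Ginv = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.dim, self.dim),
        )
        return Ginv, logdetG

    def _setup_absorption(self):
        """Plan Schur-complement absorption of the largest diagonal block.

        Every non-us2 random term has a diagonal block in C (a record
        loads on exactly one of its levels), so the biggest such term —
        typically genotype-by-location — can be eliminated analytically,
        shrinking the matrix handed to the sparse factorization by as much
        as two thirds.  Only planned for diagonal-residual problems; the
        absorbed block must be verified diagonal in every Gram piece.
        """
        self._absorb = None
        if self.rmeta.structure != "sci" or self.dim <= 600:
            return
        cands = [b for b in self.blocks if b.term.structure == "sci"]
        if not cands:
            return
        best = max(cands, key=lambda b: b.n_base)
        if best.n_base < 0.25 * self.dim:
            return
        a_idx = np.arange(self.p + best.col_slice.start, self.p + best.col_slice.stop)
        mask = np.zeros(self.dim, dtype=bool)
        mask[a_idx] = True
        r_idx = np.where(~mask)[0]
        split = []
        for Gg in self._grams:
            Gaa = Gg[a_idx][:, a_idx].tocsc()
            offdiag = Gaa - sp.diags(Gaa.diagonal())
            if offdiag.nnz and np.max(np.abs(offdiag.data)) > 0:
                return  # absorbed block not diagonal; keep the plain path
            split.append(
                (
                    np.asarray(Gaa.diagonal()).copy(),
                    Gg[r_idx][:, a_idx].tocsr(),
                    Gg[r_idx][:, r_idx].tocsc(),
                )
            )
        self._absorb = {"block": best, "a": a_idx, "r": r_idx, "split": split}

    def factorize(self, vc: VarianceComponents):
        """Factor the MME coefficient matrix at the given components."""
        if self._absorb is not None:
            return self._factorize_absorbed(vc)
        rp = self._r_pieces(vc)
        gi = self._ginv(vc)
        if rp is None or gi is None:
            return None
        A, rhs, yy, logdetR = rp
        Ginv, logdetG = gi
        C = (A + Ginv).tocsc()
        return _MMESolution(self, C, rhs, yy, logdetR, logdetG, keep_C=True)

    def _factorize_absorbed(self, vc: VarianceComponents):
        rc = self._r_coefs(vc)
        gi = self._ginv(vc)
        if rc is None or gi is None:
            return None
        coefs, rhs, yy, logdetR = rc
        Ginv, logdetG = gi
        ab = self._absorb
        a_idx, r_idx, split = ab["a"], ab["r"], ab["split"]
        gdiag = np.asarray(Ginv.diagonal())
        da = gdiag[a_idx].copy()
        B = None
        Crr = Ginv[r_idx][:, r_idx].tocsc()
        for c, (diag_a, Gar, Grr) in zip(coefs, split):
            da += c * diag_a
            B = c * Gar if B is None else B + c * Gar
            Crr = Crr + c * Grr
        if np.any(da <= 0):
            return None
        S = (Crr - (B.multiply(1.0 / da)) @ B.T).tocsc()
        return _MMESolution(
            self, None, rhs, yy, logdetR, logdetG,
            absorbed=(da, B.tocsr(), S, a_idx, r_idx),
        )

    def neg2_restricted_loglik(self, vc: VarianceComponents) -> float:
        sol = self.factorize(vc)
        if sol is None or not sol.ok:
            return _BIG
        return sol.neg2

    def col_indices(self, labels) -> np.ndarray:
        index = {l: i for i, l in enumerate(self.col_labels)}
        return np.array([index[l] for l in labels], dtype=int)

    def ai_capable(self) -> bool:
        """Whether exact scores / average information can be computed."""
        return self._absorb is not None or self.dim <= 1600

    def _rinv_apply(self, vc: VarianceComponents):
        """Returns a function v -> R^-1 v for the current residual values."""
        rm = self.rmeta
        if rm.structure == "us2":
            v1 = vc[f"sigma2_GLY':{rm.groups[0]}"]
            v2 = vc[f"sigma2_GLY':{rm.groups[1]}"]
            r = vc["rho_GLY'"]
            Sinv = _sigma_inv(v1, v2, r)
            p1, p2 = rm.pair_rows
            u1, u2 = rm.unpaired_rows

            def apply(v):
                out = np.empty_like(v, dtype=float)
                out[p1] = Sinv[0, 0] * v[p1] + Sinv[0, 1] * v[p2]
                out[p2] = Sinv[0, 1] * v[p1] + Sinv[1, 1] * v[p2]
                if len(u1):
                    out[u1] = v[u1] / v1
                if len(u2):
                    out[u2] = v[u2] / v2
                return out

            return apply
        diag = np.empty(self.n)
        for g, grp in enumerate(rm.groups):
            key = "sigma2_GLY'" if rm.structure == "sci" else f"sigma2_GLY':{grp}"
            diag[rm.group_rows[g]] = 1.0 / vc[key]
        return lambda v: diag * v

    def _z_cols(self, start: int, stop: int):
        key = (start, stop)
        if not hasattr(self, "_zc"):
            self._zc = {}
        if key not in self._zc:
            self._zc[key] = self.Z[:, start:stop].tocsc()
        return self._zc[key]

    def term_labels(self, term: str, group: str | None = None) -> list[str]:
        """Column labels of a random term (one group's half for us2)."""
        for blk in self.blocks:
            if blk.term.name == term:
                labs = blk.labels
                if blk.term.structure == "us2" and group is not None:
                    prefix = f"{term}[{group}:"
                    labs = [l for l in labs if l.startswith(prefix)]
                elif group is not None:
                    labs = [l for l in labs if f"[{group}" in l or f":{group}" in l]
                return labs
        raise KeyError(f"no random term '{term}'")


class _MMESolution:
    """A factorized coefficient matrix with solve/log-det/inverse access.

    Either holds a factorization of the full matrix C, or — when the
    problem absorbed its largest diagonal block — the absorbed diagonal
    ``da``, coupling block ``B`` and a factorization of the Schur
    complement ``S``; both representations expose the same solve / log-det
    / inverse-block interface.
    """

    def __init__(self, prob: MMEProblem, C, rhs, yy, logdetR, logdetG,
                 absorbed=None, keep_C=False):
        self.prob = prob
        self.rhs = rhs
        self.ok = True
        self._ab = absorbed
        self._C = C if keep_C else None
        self._cinv_cache = None
        if absorbed is None:
            if not self._factor_matrix(C, attr="_main"):
                return
            self.logdetC = self._main_logdet
        else:
            da, B, S, a_idx, r_idx = absorbed
            if not self._factor_matrix(S, attr="_main"):
                return
            self.logdetC = float(np.sum(np.log(da))) + self._main_logdet
        self.sol = self.solve(rhs)
        ypy = yy - float(rhs @ self.sol)
        n, p = prob.n, prob.p
        self.neg2 = logdetR + logdetG + self.logdetC + ypy + (n - p) * _LOG2PI

    def _factor_matrix(self, M, attr: str) -> bool:
        dim = M.shape[0]
        if dim <= 500:
            try:
                chol = sla.cho_factor(M.toarray() if sp.issparse(M) else M, lower=True)
            except sla.LinAlgError:
                self.ok = False
                return False
            self._main_solve = lambda b: sla.cho_solve(chol, b)
            self._main_logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
            return True
        try:
            lu = spla.splu(M.tocsc(), permc_spec="MMD_AT_PLUS_A")
        except RuntimeError:
            self.ok = False
            return False
        d = lu.U.diagonal()
        if np.any(d <= 0):
            # sign flips can come from pivoting; C itself is PD here
            d = np.abs(d)

        def _solve(b, lu=lu):
            if b.ndim == 1:
                return lu.solve(b)
            return np.column_stack([lu.solve(b[:, j]) for j in range(b.shape[1])])

        self._main_solve = _solve
        self._main_logdet = float(np.sum(np.log(d)))
        return True

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self._ab is None:
            return self._main_solve(b)
        da, B, S, a_idx, r_idx = self._ab
        if b.ndim == 1:
            ba, br = b[a_idx], b[r_idx]
            xr = self._main_solve(br - B @ (ba / da))
            xa = (ba - B.T @ xr) / da
            out = np.empty_like(b, dtype=float)
        else:
            ba, br = b[a_idx, :], b[r_idx, :]
            xr = self._main_solve(br - B @ (ba / da[:, None]))
            xa = (ba - B.T @ xr) / da[:, None]
            out = np.empty_like(b, dtype=float)
        out[a_idx] = xa
        out[r_idx] = xr
        return out

    def dense_inverse(self) -> np.ndarray:
        return self.solve(np.eye(self.prob.dim))

    # -- trace access for the average-information algorithm ----------------

    def _core_inverse(self) -> np.ndarray:
        """Dense inverse of the factored core (S for absorbed, C otherwise)."""
        if self._cinv_cache is None:
            if self._ab is not None:
                S = self._ab[2]
                chol = sla.cho_factor(S.toarray(), lower=True)
                self._cinv_cache = sla.cho_solve(chol, np.eye(S.shape[0]))
            elif self._C is not None:
                chol = sla.cho_factor(self._C.toarray(), lower=True)
                self._cinv_cache = sla.cho_solve(chol, np.eye(self.prob.dim))
            else:
                self._cinv_cache = self.dense_inverse()
        return self._cinv_cache

    def _pos_map(self) -> np.ndarray:
        """Map full MME column index -> position in the factored core."""
        if self._ab is None:
            return np.arange(self.prob.dim)
        pos = np.full(self.prob.dim, -1, dtype=int)
        pos[self._ab[4]] = np.arange(len(self._ab[4]))
        return pos

    def block_trace(self, idx1: np.ndarray, idx2: np.ndarray | None = None) -> float:
        """sum_k Cinv[idx1[k], idx2[k]] for non-absorbed columns."""
        cinv = self._core_inverse()
        pos = self._pos_map()
        i1 = pos[idx1]
        i2 = i1 if idx2 is None else pos[idx2]
        if np.any(i1 < 0) or np.any(i2 < 0):
            raise ValueError("trace requested over absorbed columns")
        return float(cinv[i1, i2].sum())

    def absorbed_trace(self) -> float:
        """tr of the absorbed block of C^-1."""
        da, B, S, a_idx, r_idx = self._ab
        K = B.multiply(1.0 / da).tocsr()
        T2 = (K @ K.T).tocoo()
        cinv = self._core_inverse()
        return float(np.sum(1.0 / da) + np.sum(cinv[T2.row, T2.col] * T2.data))

    def gram_trace(self, gram) -> float:
        """sum(Cinv o gram) for a full-dimension Gram piece (plain path)."""
        if self._ab is not None:
            raise ValueError("gram_trace unavailable on the absorbed path")
        cinv = self._core_inverse()
        g = gram.tocoo()
        return float(np.sum(cinv[g.row, g.col] * g.data))

    def inverse_block(self, labels) -> np.ndarray:
        """Rows/columns of C^-1 for the named MME columns."""
        idx = self.prob.col_indices(labels)
        E = np.zeros((self.prob.dim, len(idx)))
        E[idx, np.arange(len(idx))] = 1.0
        return self.solve(E)[idx, :]

    @property
    def fixed_effects(self) -> np.ndarray:
        return self.sol[: self.prob.p]

    @property
    def blups(self) -> np.ndarray:
        return self.sol[self.prob.p:]


# ---------------------------------------------------------------------------
# Average-information REML
# ---------------------------------------------------------------------------

def _sigma_inv(v1, v2, r):
    det = v1 * v2 * (1.0 - r * r)
    return np.array(
        [[v2 / det, -r * np.sqrt(v1 * v2) / det],
         [-r * np.sqrt(v1 * v2) / det, v1 / det]]
    )


def _us2_derivs(v1, v2, r):
    """d Sigma / d(v1, v2, rho) for a 2x2 unstructured block."""
    s = np.sqrt(v1 * v2)
    return {
        0: np.array([[1.0, 0.5 * r * np.sqrt(v2 / v1)],
                     [0.5 * r * np.sqrt(v2 / v1), 0.0]]),
        1: np.array([[0.0, 0.5 * r * np.sqrt(v1 / v2)],
                     [0.5 * r * np.sqrt(v1 / v2), 1.0]]),
        2: np.array([[0.0, s], [s, 0.0]]),
    }


def _ai_scores(prob: MMEProblem, sol, vc: VarianceComponents):
    """Exact REML score per parameter plus the working vectors V-dot @ Py.

    Scores use the classic MME trace identities: for a random term t,
    Z_t' P Z_t = G_t^-1 - G_t^-1 (Cinv)_tt G_t^-1, so every trace reduces
    to block traces of the inverse coefficient matrix; the residual trace
    follows from tr(PV) = n - p.  Returns (scores, fvecs, Py) keyed by
    parameter name; scores are d l_R / d theta.
    """
    apply_rinv = prob._rinv_apply(vc)
    ehat = prob.y - prob.W @ sol.sol
    Py = apply_rinv(ehat)
    scores: dict[str, float] = {}
    fvecs: dict[str, np.ndarray] = {}
    s_terms = 0.0  # sum_t tr(P Z_t G_t Z_t') for the residual identity

    for blk in prob.blocks:
        t = blk.term
        off = prob.p + blk.col_slice.start
        Zt = prob._z_cols(blk.col_slice.start, blk.col_slice.stop)
        zpy = Zt.T @ Py
        if t.structure == "sci":
            v = vc[f"sigma2_{t.name}"]
            idx = np.arange(off, off + blk.n_base)
            trc = sol.absorbed_trace() if (
                sol._ab is not None and off == sol._ab[3][0]
            ) else sol.block_trace(idx)
            tr_pv = blk.n_base / v - trc / v**2
            s_terms += blk.n_base - trc / v
            f = Zt @ zpy
            scores[f"sigma2_{t.name}"] = -0.5 * (tr_pv - float(Py @ f))
            fvecs[f"sigma2_{t.name}"] = f
        elif t.structure == "group_diag":
            for gi, g in enumerate(blk.groups):
                sel = np.where(blk.group_of_col == gi)[0]
                v = vc[f"sigma2_{t.name}:{g}"]
                idx = off + sel
                trc = sol.block_trace(idx)
                tr_pv = len(sel) / v - trc / v**2
                s_terms += len(sel) - trc / v
                zg = np.zeros_like(zpy)
                zg[sel] = zpy[sel]
                f = Zt @ zg
                scores[f"sigma2_{t.name}:{g}"] = -0.5 * (tr_pv - float(Py @ f))
                fvecs[f"sigma2_{t.name}:{g}"] = f
        else:  # us2
            g1n, g2n = blk.groups
            v1 = vc[f"sigma2_{t.name}:{g1n}"]
            v2 = vc[f"sigma2_{t.name}:{g2n}"]
            r = vc[f"rho_{t.name}"]
            m = blk.n_base
            i1 = np.arange(off, off + m)
            i2 = np.arange(off + m, off + 2 * m)
            tr11 = sol.block_trace(i1)
            tr22 = sol.block_trace(i2)
            tr12 = sol.block_trace(i1, i2)
            Sinv = _sigma_inv(v1, v2, r)
            s_terms += 2 * m - (
                Sinv[0, 0] * tr11 + Sinv[1, 1] * tr22 + 2 * Sinv[0, 1] * tr12
            )
            derivs = _us2_derivs(v1, v2, r)
            names = [f"sigma2_{t.name}:{g1n}", f"sigma2_{t.name}:{g2n}",
                     f"rho_{t.name}"]
            for k, nm in enumerate(names):
                E = derivs[k]
                K = Sinv @ E @ Sinv
                tr_pv = m * float(np.trace(Sinv @ E)) - (
                    K[0, 0] * tr11 + K[1, 1] * tr22 + 2 * K[0, 1] * tr12
                )
                h1 = E[0, 0] * zpy[:m] + E[0, 1] * zpy[m:]
                h2 = E[0, 1] * zpy[:m] + E[1, 1] * zpy[m:]
                f = Zt @ np.concatenate([h1, h2])
                scores[nm] = -0.5 * (tr_pv - float(Py @ f))
                fvecs[nm] = f

    rm = prob.rmeta
    if rm.structure == "sci":
        v = vc["sigma2_GLY'"]
        tr_p = (prob.n - prob.p - s_terms) / v
        f = Py
        scores["sigma2_GLY'"] = -0.5 * (tr_p - float(Py @ f))
        fvecs["sigma2_GLY'"] = f
    elif rm.structure == "group_diag":  # plain dense path only
        for g, grp in enumerate(rm.groups):
            v = vc[f"sigma2_GLY':{grp}"]
            trg = sol.gram_trace(prob._grams[g])
            tr_p = prob._nrows[g] / v - trg / v**2
            f = np.zeros(prob.n)
            f[rm.group_rows[g]] = Py[rm.group_rows[g]]
            scores[f"sigma2_GLY':{grp}"] = -0.5 * (tr_p - float(Py @ f))
            fvecs[f"sigma2_GLY':{grp}"] = f
    else:  # us2 residual (paired traits); plain dense path only
        g1n, g2n = rm.groups
        v1 = vc[f"sigma2_GLY':{g1n}"]
        v2 = vc[f"sigma2_GLY':{g2n}"]
        r = vc["rho_GLY'"]
        Sinv = _sigma_inv(v1, v2, r)
        p1, p2 = rm.pair_rows
        u1, u2 = rm.unpaired_rows
        G11, G22, G12 = prob._pair[0], prob._pair[1], prob._pair[2]
        npair = prob._pair[10]
        gt11 = sol.gram_trace(G11)
        gt22 = sol.gram_trace(G22)
        gt12 = sol.gram_trace(G12) + sol.gram_trace(G12.T)
        gtu = [sol.gram_trace(g) if n else 0.0
               for g, n in zip(prob._grams, prob._nrows)]
        derivs = _us2_derivs(v1, v2, r)
        names = [f"sigma2_GLY':{g1n}", f"sigma2_GLY':{g2n}", "rho_GLY'"]
        for k, nm in enumerate(names):
            E = derivs[k]
            K = Sinv @ E @ Sinv
            tr_rv = npair * float(np.trace(Sinv @ E))
            tr_wcw = K[0, 0] * gt11 + K[1, 1] * gt22 + K[0, 1] * gt12
            if k == 0 and len(u1):
                tr_rv += len(u1) / v1
                tr_wcw += gtu[0] / v1**2
            if k == 1 and len(u2):
                tr_rv += len(u2) / v2
                tr_wcw += gtu[1] / v2**2
            f = np.zeros(prob.n)
            f[p1] = E[0, 0] * Py[p1] + E[0, 1] * Py[p2]
            f[p2] = E[0, 1] * Py[p1] + E[1, 1] * Py[p2]
            if k == 0 and len(u1):
                f[u1] = Py[u1]
            if k == 1 and len(u2):
                f[u2] = Py[u2]
            scores[nm] = -0.5 * (tr_rv - tr_wcw - float(Py @ f))
            fvecs[nm] = f
    return scores, fvecs, Py, apply_rinv


def _apply_P(prob: MMEProblem, sol, apply_rinv, v: np.ndarray) -> np.ndarray:
    u = apply_rinv(v)
    return u - apply_rinv(prob.W @ sol.solve(prob.W.T @ u))


def _ai_fit(prob: MMEProblem, vc0: VarianceComponents, free: list[str],
            options: "FitOptions", s2y: float):
    """Average-information REML with exact scores and step halving.

    Variances that collapse toward zero are pinned at a small floor
    (reported downstream as zero-bounded); the inverse AI matrix of the
    active parameters at convergence approximates their sampling
    covariance.
    """
    vc = VarianceComponents(vc0)
    floor = 1e-10 * s2y
    pinned: set[str] = set()
    sol = prob.factorize(vc)
    if sol is None or not sol.ok:
        return vc, None, False, 0, sol
    neg2 = sol.neg2
    ai_cov = None
    converged = False
    it = 0
    for it in range(1, options.ai_max_iter + 1):
        scores, fvecs, Py, rinv = _ai_scores(prob, sol, vc)
        # release pinned components whose score turned positive again
        for nm in list(pinned):
            if scores.get(nm, 0.0) > 0:
                pinned.discard(nm)
        act = [nm for nm in free if nm not in pinned]
        if not act:
            converged = True
            break
        pf = {nm: _apply_P(prob, sol, rinv, fvecs[nm]) for nm in act}
        AI = np.array([[0.5 * float(fvecs[a] @ pf[b]) for b in act] for a in act])
        AI = 0.5 * (AI + AI.T)
        g = np.array([scores[nm] for nm in act])
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(len(act)), g)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(AI) @ g
        # trust-region cap: an ill-conditioned AI matrix near a correlation
        # boundary can propose steps many orders beyond the parameter scale
        cap = np.array([
            0.5 if nm.startswith("rho_") else 4.0 * (abs(vc[nm]) + 1e-4 * s2y)
            for nm in act
        ])
        with np.errstate(divide="ignore"):
            shrink = float(np.min(np.where(np.abs(delta) > 0, cap / np.abs(delta), 1.0)))
        delta = delta * min(1.0, shrink)

        def try_direction(direction):
            step = 1.0
            for _ in range(40):
                trial = VarianceComponents(vc)
                valid = True
                for nm, d in zip(act, direction):
                    val = vc[nm] + step * d
                    if nm.startswith("rho_"):
                        val = float(np.clip(val, -0.999, 0.999))
                    elif val <= 0:
                        valid = False
                        break
                    trial[nm] = float(val)
                if valid:
                    sol_t = prob.factorize(trial)
                    if sol_t is not None and sol_t.ok and sol_t.neg2 <= neg2 + 1e-9:
                        return trial, sol_t
                step /= 2.0
            return None, None

        trial, sol_t = try_direction(delta)
        if trial is None:
            # fall back to a scaled steepest-ascent step
            gdir = g.copy()
            mx = np.max(np.abs(gdir))
            if mx > 0:
                gdir = gdir / mx * 0.1 * np.minimum(
                    cap, np.array([abs(vc[nm]) + 1e-4 * s2y for nm in act])
                )
                trial, sol_t = try_direction(gdir)
        if trial is None:
            converged = True  # no uphill step at line-search resolution
            break
        improvement = neg2 - sol_t.neg2
        rel = max(
            abs(trial[nm] - vc[nm]) / (abs(vc[nm]) + 1e-3 * s2y) for nm in act
        )
        vc, sol, neg2 = trial, sol_t, sol_t.neg2
        # pin variances collapsing to the boundary
        for nm in act:
            if not nm.startswith("rho_") and vc[nm] < floor:
                vc[nm] = floor
                pinned.add(nm)
        if improvement < 1e-9 and rel < 1e-7:
            converged = True
            break
    # covariance of active parameters from the final AI matrix
    scores, fvecs, Py, rinv = _ai_scores(prob, sol, vc)
    act = [nm for nm in free if nm not in pinned]
    if act:
        pf = {nm: _apply_P(prob, sol, rinv, fvecs[nm]) for nm in act}
        AI = np.array([[0.5 * float(fvecs[a] @ pf[b]) for b in act] for a in act])
        ai_cov = pd.DataFrame(np.linalg.pinv(0.5 * (AI + AI.T)), index=act, columns=act)
    return vc, ai_cov, converged, it, sol


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FitOptions:
    method: str = "auto"  # auto | ai | search
    max_iter: int = 200
    gtol: float = 1e-7
    ftol: float = 1e-11
    polish: bool | None = None  # default: simplex polish when <= 6 free params
    polish_xatol: float = 1e-11
    rho_bound: float = 5.0  # bound on atanh(rho); rho within ~0.9999
    ai_max_iter: int = 80


@dataclasses.dataclass
class FitResult:
    """REML solution: components, fixed effects, BLUPs, and MME access."""

    spec: ModelSpec
    vc: VarianceComponents
    fixed_effects: pd.Series
    fixed_se: pd.Series
    blups: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    message: str
    zero_bounded: list[str]
    boundary_params: list[str]
    problem: MMEProblem = dataclasses.field(repr=False, default=None)
    solution: "_MMESolution" = dataclasses.field(repr=False, default=None)
    ai_cov: pd.DataFrame | None = dataclasses.field(repr=False, default=None)

    def refit_solution(self, vc: VarianceComponents) -> _MMESolution:
        """Re-solve the MME with components frozen at ``vc`` (no REML)."""
        sol = self.problem.factorize(vc)
        if sol is None or not sol.ok:
            raise ValueError("coefficient matrix singular at supplied components")
        return sol


def _pack(vc, params, free, s2y, rho_bound):
    x = []
    for p in params:
        if p.name not in free:
            continue
        v = vc[p.name]
        if p.kind == "var":
            x.append(np.log(max(v, 1e-12 * s2y)))
        else:
            x.append(np.clip(np.arctanh(np.clip(v, -0.999999, 0.999999)),
                             -rho_bound, rho_bound))
    return np.array(x)


def _unpack(x, params, free, fixed_vals):
    vc = VarianceComponents()
    i = 0
    for p in params:
        if p.name in free:
            vc[p.name] = float(np.exp(x[i])) if p.kind == "var" else float(np.tanh(x[i]))
            i += 1
        else:
            vc[p.name] = float(fixed_vals[p.name])
    return vc


def build_problem(df: pd.DataFrame, spec: ModelSpec) -> MMEProblem:
    y = response_vector(df)
    X, x_names = build_fixed_matrix(df, spec.fixed)
    Z, blocks = build_random_matrix(df, spec.random)
    rmeta = _residual_meta(df, spec.residual)
    return MMEProblem(y, X, x_names, Z, blocks, rmeta)


def reml_fit(
    data: METDataset | pd.DataFrame,
    spec: ModelSpec,
    *,
    init: dict | None = None,
    fix: dict | None = None,
    options: FitOptions | None = None,
    registration_years: dict[str, int] | None = None,
) -> FitResult:
    """Estimate variance components by REML and solve the MME at the optimum.

    ``fix`` freezes named components/correlations (natural scale) — used for
    the zero-correlation counterfactual and for constrained fits in
    likelihood-ratio tests.  ``init`` provides starting values by name.
    The result is deterministic given data, init and options.
    """
    options = options or FitOptions()
    if isinstance(data, METDataset):
        df = prepare_frame(data, registration_years=registration_years)
    else:
        df = data[np.isfinite(data["value"])].reset_index(drop=True)
    prob = build_problem(df, spec)
    params = prob.params
    fix = dict(fix or {})
    unknown = set(fix) - set(prob.param_names)
    if unknown:
        raise KeyError(f"fix refers to unknown parameters: {sorted(unknown)}")
    free = [p.name for p in params if p.name not in fix]

    s2y = float(np.var(prob.y)) or 1.0
    # per-residual-group response variance, for scale-aware starting values
    # (traits/countries can differ in scale by orders of magnitude)
    s2_group = {}
    for g, grp in enumerate(prob.rmeta.groups):
        rows = (
            prob.rmeta.group_rows[g]
            if prob.rmeta.structure != "us2"
            else np.concatenate(
                [prob.rmeta.pair_rows[g], prob.rmeta.unpaired_rows[g]]
            ).astype(int)
        )
        s2_group[grp] = float(np.var(prob.y[rows])) or s2y
    n_var_terms = max(1, len({p.term for p in params}))
    vc0 = VarianceComponents()
    for p in params:
        if p.name in fix:
            vc0[p.name] = fix[p.name]
        elif init and p.name in init:
            vc0[p.name] = init[p.name]
        elif p.kind == "var":
            suffix = p.name.split(":", 1)[1] if ":" in p.name else None
            scale = s2_group.get(suffix, s2y)
            vc0[p.name] = (
                scale / 2.0 if p.term == "GLY'" else scale / (2.0 * n_var_terms)
            )
        else:
            vc0[p.name] = 0.0

    if not free:
        sol = prob.factorize(vc0)
        return _finalize(prob, spec, vc0, sol, True, 0, "all components fixed", s2y)

    method = options.method
    if method == "auto":
        method = "ai" if (prob.dim > 450 and prob.ai_capable()) else "search"
    if method == "ai":
        if not prob.ai_capable():
            raise ValueError("average-information scores unavailable for this model")
        vc_hat, ai_cov, converged, n_iter, sol = _ai_fit(prob, vc0, free, options, s2y)
        res = _finalize(prob, spec, vc_hat, sol, converged, n_iter,
                        "AI-REML", s2y, rho_bound=options.rho_bound)
        res.ai_cov = ai_cov
        return res

    x0 = _pack(vc0, params, set(free), s2y, options.rho_bound)
    bounds = []
    for p in params:
        if p.name not in free:
            continue
        if p.kind == "var":
            # lower bound keeps the MME numerically factorable even when a
            # component collapses to the zero boundary (reported as
            # zero-bounded downstream)
            bounds.append((np.log(s2y) - 16.0, np.log(s2y) + 12.0))
        else:
            bounds.append((-options.rho_bound, options.rho_bound))

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x):
        # the simplex polish is unbounded; keep it inside the box
        vc = _unpack(np.clip(x, lo, hi), params, set(free), fix)
        return prob.neg2_restricted_loglik(vc)

    res = opt.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=options.max_iter, ftol=options.ftol, gtol=options.gtol),
    )
    x_hat, n_iter, converged, msg = res.x, res.nit, bool(res.success), str(res.message)

    do_polish = options.polish if options.polish is not None else len(free) <= 6
    if do_polish:
        res2 = opt.minimize(
            objective, x_hat, method="Nelder-Mead",
            options=dict(
                xatol=options.polish_xatol, fatol=1e-12, maxiter=4000, maxfev=8000
            ),
        )
        if res2.fun <= res.fun:
            x_hat = res2.x
            converged = converged or bool(res2.success)
            n_iter += res2.nit

    vc_hat = _unpack(np.clip(x_hat, lo, hi), params, set(free), fix)
    vc_hat = _em_refine(prob, vc_hat, set(free), floor=1e-10 * s2y)
    sol = prob.factorize(vc_hat)
    return _finalize(prob, spec, vc_hat, sol, converged, n_iter, msg, s2y,
                     rho_bound=options.rho_bound)


def _em_refine(prob: MMEProblem, vc: VarianceComponents, free: set,
               max_iter: int = 5000, tol: float = 5e-13,
               floor: float = 0.0) -> VarianceComponents:
    """Exact fixed-point (EM-REML) refinement of the search optimum.

    The quasi-Newton/simplex search locates the optimum only to the
    precision at which likelihood differences survive floating point
    (~1e-7 in the parameters).  The REML score equations, expressed through
    the dense inverse of the MME coefficient matrix,

        sigma2_t  <- (u_t'u_t + tr(Cinv_tt)) / q_t          (random terms)
        Sigma_t   <- (U_t'U_t + blocktrace(Cinv_t)) / m_t   (us2 blocks)
        sigma2_eg <- (e_g'e_g + tr(Cinv W_g'W_g)) / n_g     (residual groups)

    have the REML estimate as their fixed point; iterating them polishes
    the components to near machine precision.  Applied only to small dense
    problems with a diagonal-structure residual; terms with any frozen
    parameter are left untouched.
    """
    if prob.dim > 600 or prob.rmeta.structure == "us2":
        return vc
    # terms whose every parameter is free get EM updates
    updatable = []
    for blk in prob.blocks:
        names = param_names(blk.term, blk.groups)
        if all(n in free for n in names):
            updatable.append(blk)
    rm = prob.rmeta
    resid_names = (
        ["sigma2_GLY'"] if rm.structure == "sci"
        else [f"sigma2_GLY':{g}" for g in rm.groups]
    )
    update_resid = all(n in free for n in resid_names)
    if not updatable and not update_resid:
        return vc

    y, W, p = prob.y, prob.W, prob.p
    for _ in range(max_iter):
        sol = prob.factorize(vc)
        if sol is None or not sol.ok:
            return vc
        Cinv = sol.dense_inverse()
        ehat = y - W @ sol.sol
        new = VarianceComponents(vc)
        for blk in updatable:
            off = p + blk.col_slice.start
            t = blk.term
            if t.structure == "sci":
                idx = np.arange(off, off + blk.n_base)
                u = sol.sol[idx]
                new[f"sigma2_{t.name}"] = max(float(
                    (u @ u + np.trace(Cinv[np.ix_(idx, idx)])) / blk.n_base
                ), floor)
            elif t.structure == "group_diag":
                for gi, g in enumerate(blk.groups):
                    idx = off + np.where(blk.group_of_col == gi)[0]
                    u = sol.sol[idx]
                    new[f"sigma2_{t.name}:{g}"] = max(float(
                        (u @ u + np.trace(Cinv[np.ix_(idx, idx)])) / len(idx)
                    ), floor)
            else:  # us2
                m = blk.n_base
                i1 = np.arange(off, off + m)
                i2 = np.arange(off + m, off + 2 * m)
                U = np.column_stack([sol.sol[i1], sol.sol[i2]])
                tr11 = float(np.trace(Cinv[np.ix_(i1, i1)]))
                tr22 = float(np.trace(Cinv[np.ix_(i2, i2)]))
                tr12 = float(Cinv[i1, i2].sum())
                S = (U.T @ U + np.array([[tr11, tr12], [tr12, tr22]])) / m
                v1, v2 = max(S[0, 0], floor, 1e-300), max(S[1, 1], floor, 1e-300)
                new[f"sigma2_{t.name}:{blk.groups[0]}"] = v1
                new[f"sigma2_{t.name}:{blk.groups[1]}"] = v2
                new[f"rho_{t.name}"] = float(
                    np.clip(S[0, 1] / np.sqrt(v1 * v2), -0.999999, 0.999999)
                )
        if update_resid:
            for g, (gram, nrows) in enumerate(zip(prob._grams, prob._nrows)):
                rows = rm.group_rows[g]
                eg = ehat[rows]
                tr = float(np.sum(Cinv * gram.toarray()))
                new[resid_names[g]] = max(float((eg @ eg + tr) / nrows), floor)
        rel = max(
            abs(new[k] - vc[k]) / max(abs(vc[k]), 1e-300) for k in new
        )
        vc = new
        if rel < tol:
            break
    return vc


def _finalize(prob, spec, vc, sol, converged, n_iter, msg, s2y, rho_bound=5.0):
    if sol is None or not sol.ok:
        raise ValueError("coefficient matrix singular at the fitted components")
    fixed = pd.Series(sol.fixed_effects, index=prob.x_names)
    fixed_cov = sol.inverse_block(prob.x_names)
    fixed_se = pd.Series(np.sqrt(np.maximum(np.diag(fixed_cov), 0.0)),
                         index=prob.x_names)
    blups = pd.Series(sol.blups, index=prob.col_labels[prob.p:])
    zero_bounded = [
        p.name for p in prob.params
        if p.kind == "var" and vc[p.name] < 1e-7 * s2y
    ]
    boundary = [
        p.name for p in prob.params
        if p.kind == "rho" and abs(vc[p.name]) > np.tanh(rho_bound) - 1e-9
    ]
    return FitResult(
        spec=spec, vc=vc, fixed_effects=fixed, fixed_se=fixed_se, blups=blups,
        loglik=-0.5 * sol.neg2, converged=converged, n_iter=n_iter,
        n_obs=prob.n, message=msg, zero_bounded=zero_bounded,
        boundary_params=boundary, problem=prob, solution=sol,
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def blup_diff_variance(fit: FitResult, term: str = "G", group: str | None = None) -> float:
    """Average variance of a difference between two varieties' BLUPs.

    Computed from the genotypic block of the generalized inverse of the MME
    coefficient matrix; this is the numerator quantity of the generalized
    (Cullis) heritability.
    """
    labels = fit.problem.term_labels(term, group)
    m = len(labels)
    if m < 2:
        raise ValueError("need at least two varieties")
    P = fit.solution.inverse_block(labels)
    tr = float(np.trace(P))
    total = float(P.sum())
    # mean over pairs (i < j) of P_ii + P_jj - 2 P_ij
    return (2.0 / (m * (m - 1))) * ((m - 1) * tr - (total - tr))


def pairwise_sed_matrix(sol: _MMESolution, labels) -> np.ndarray:
    """SED(i, i') of random-effect differences for the named MME columns."""
    P = sol.inverse_block(labels)
    d = np.diag(P)
    sed2 = d[:, None] + d[None, :] - 2.0 * P
    return np.sqrt(np.maximum(sed2, 0.0))


def lrt_correlation(fit_full: FitResult, fit_constrained: FitResult) -> float:
    """Likelihood-ratio p-value for one correlation fixed at zero.

    The constrained fit must nest the full fit with exactly one correlation
    frozen; the statistic is referred to a chi-square with 1 df, with
    negative statistics clamped to zero.
    """
    if fit_full.problem.param_names != fit_constrained.problem.param_names:
        raise ValueError("fits are not nested: different parameter sets")
    stat = 2.0 * (fit_full.loglik - fit_constrained.loglik)
    return float(chi2.sf(max(stat, 0.0), df=1))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR adjustment of a family of p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def wald_p(estimate: float, se: float) -> float:
    if se <= 0:
        return float("nan")
    return float(2.0 * norm.sf(abs(estimate) / se))


def satterthwaite_df(fit: FitResult, coef: str) -> float:
    """Satterthwaite denominator degrees of freedom for a fixed coefficient.

    df = 2 Var(b)^2 / Var(Var(b)), with the variance of the plug-in
    coefficient variance obtained by the delta method: a finite-difference
    gradient of Var(b) with respect to the variance parameters, combined
    with their average-information covariance.  The plug-in Wald z test is
    anti-conservative for covariates whose replication is governed by a
    variance component estimated near its boundary (a trend over 10-16
    years, say); the t reference with this df restores calibration.
    Falls back to +inf (the normal reference) when no AI covariance is
    available.
    """
    if fit.ai_cov is None or coef not in fit.fixed_effects.index:
        return float("inf")
    prob = fit.problem
    names = [n for n in fit.ai_cov.index]
    s2 = float(fit.fixed_se[coef]) ** 2
    base = dict(fit.vc)

    def coef_var(vc):
        sol = prob.factorize(VarianceComponents(vc))
        if sol is None or not sol.ok:
            return s2
        return float(sol.inverse_block([coef])[0, 0])

    g = []
    for nm in names:
        h = max(1e-7, 1e-3 * abs(base[nm]))
        up = dict(base)
        up[nm] += h
        g.append((coef_var(up) - s2) / h)
    g = np.asarray(g)
    V = fit.ai_cov.loc[names, names].to_numpy()
    denom = float(g @ V @ g)
    if denom <= 0:
        return float("inf")
    return max(2.0 * s2 * s2 / denom, 1.0)
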