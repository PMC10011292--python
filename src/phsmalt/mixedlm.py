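"""Restricted maximum likelihood (REML) for the Gaussian mixed-model family
used throughout the package, with likelihood-ratio and Wald inference.

The engine covers models of the form

    y = X beta + Z u + e,   u ~ N(0, G),   e ~ N(0, R)

where the random structure G per grouping factor is one of

* ``IID``   - a single variance sigma2 for all levels,
* ``DIAG``  - one variance per level of a stratifying factor (e.g. a line
  variance per selection cycle, or independent line effects per trait),
* ``US2``   - an unstructured 2x2 covariance across the two levels of a trait
  factor (the bivariate genetic-correlation model),

and the residual R is IID or DIAG by a stratifier (e.g. per year, or per
trait-by-year cell).

Estimation maximises the restricted log-likelihood

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

profiled through the Woodbury identity, so only the q x q matrix
W = G^-1 + Z' R^-1 Z is ever factorised.  W decomposes into small independent
blocks (one per line, typically 1-4 columns) for every model in this family;
blocks are batch-factorised with LAPACK.  Variances are optimised on the log
scale (US2 via the Cholesky of the 2x2 matrix, keeping it positive
semi-definite) with analytic gradients and a quasi-Newton optimiser,
multi-started from deterministic perturbed values to guard against local
optima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2
from scipy.stats import t as t_dist

log = logging.getLogger("phsmalt")

_SEP = "\x1f"
_LOGV_LB, _LOGV_UB = -16.0, 13.0  # bounds for log-variances on unit-scaled data
_ZERO_VAR = 2e-7  # scaled variances at/near the lower bound report as 0


class ModelError(ValueError):
    """Mis-specified or non-identifiable mixed model."""


@dataclass(frozen=True)
class RandomTerm:
    """One random term: grouping factor, covariance structure, stratifier.

    ``group`` may be a single column or an interaction like ``"line:timepoint"``.
    ``by`` is the stratifying column for DIAG (one variance per level) or the
    2-level trait column for US2.
    """

    group: str
    structure: str = "IID"
    by: str | None = None

    def __post_init__(self):
        if self.structure not in ("IID", "DIAG", "US2"):
            raise ModelError(f"unknown random structure {self.structure!r}")
        if self.structure in ("DIAG", "US2") and self.by is None:
            raise ModelError(f"{self.structure} requires a 'by' stratifier")


@dataclass(frozen=True)
class Residual:
    structure: str = "IID"
    by: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.structure not in ("IID", "DIAG"):
            raise ModelError(f"unknown residual structure {self.structure!r}")
        if self.structure == "DIAG" and not self.by:
            raise ModelError("DIAG residual requires 'by' column(s)")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model."""

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()
    residual: Residual = Residual()

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        random = tuple(
            RandomTerm(r["group"], r.get("structure", "IID"), r.get("by"))
            for r in d.get("random", [])
        )
        res = d.get("residual", {})
        by = res.get("by")
        residual = Residual(
            res.get("structure", "IID"),
            tuple(by) if isinstance(by, (list, tuple)) else ((by,) if by else None),
        )
        return cls(d["response"], tuple(d.get("fixed", ())), random, residual)


@dataclass
class REMLFit:
    """A fitted mixed model: variance components, GLS fixed effects, loglik."""

    spec: ModelSpec
    fixed_estimates: pd.DataFrame  # effect, estimate, se, aliased
    varcomp: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    n_fixed: int  # rank of the fixed design
    at_bound: bool = False
    n_iter: int = 0
    aliased: tuple[str, ...] = ()
    _y_key: tuple = field(default=(), repr=False)

    def variance(self, name: str) -> float:
        return self.varcomp[name]

    @property
    def beta(self) -> pd.Series:
        return self.fixed_estimates.set_index("effect")["estimate"]


# ---------------------------------------------------------------------------
# design construction


def _factor_codes(data: pd.DataFrame, col: str):
    """Category codes and the category values themselves (original dtype, so
    new data re-encodes correctly; stringify only for labels)."""
    if col not in data.columns:
        raise ModelError(f"factor column {col!r} not present in the data")
    s = data[col]
    if isinstance(s.dtype, pd.CategoricalDtype):
        cats = [c for c in s.cat.categories if c in set(s.dropna().unique())]
    else:
        cats = sorted(pd.unique(s.dropna()), key=str)
    codes = pd.Categorical(s, categories=cats).codes.astype(np.int64)
    if (codes < 0).any():
        raise ModelError(f"missing values in factor {col!r}")
    return codes, cats


class FixedDesign:
    """Treatment-coded fixed design with intercept; aliased columns dropped.

    Interactions are products of non-reference indicator columns of their
    factors.  Rank deficiency (empty cells, confounded factors) is detected by
    pivoted QR; aliased columns are removed and reported by label.  The fitted
    category layout can re-encode new data (e.g. prediction grids) through
    :meth:`encode`.
    """

    def __init__(self, data: pd.DataFrame, terms: Sequence[str]):
        self.terms = list(terms)
        self.categories: dict[str, list[str]] = {}
        for term in self.terms:
            for pcol in term.split(":"):
                if pcol not in self.categories:
                    _, cats = _factor_codes(data, pcol)
                    self.categories[pcol] = cats
        Xfull, self.all_labels = self._encode_full(data)
        _, R, piv = sla.qr(Xfull, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag[0] * max(Xfull.shape) * np.finfo(float).eps if diag[0] > 0 else 0.0
        rank = int((diag > tol).sum())
        self.keep = np.sort(piv[:rank])
        self.aliased = [self.all_labels[j] for j in sorted(piv[rank:])]
        if self.aliased:
            log.info(
                "fixed design: %d aliased column(s) dropped: %s",
                len(self.aliased),
                self.aliased[:10],
            )
        self.X = Xfull[:, self.keep]
        self.labels = [self.all_labels[j] for j in self.keep]

    def _encode_full(self, data: pd.DataFrame):
        n = len(data)
        cols = [np.ones(n)]
        labels = ["Intercept"]
        for term in self.terms:
            parts = term.split(":")
            coded = []
            for pcol in parts:
                cats = self.categories[pcol]
                codes = pd.Categorical(data[pcol], categories=cats).codes
                coded.append(
                    [
                        (f"{pcol}[{cats[k]}]", (codes == k).astype(float))
                        for k in range(1, len(cats))
                    ]
                )
            combos = coded[0]
            for nxt in coded[1:]:
                combos = [(f"{la}:{lb}", a * b) for la, a in combos for lb, b in nxt]
            for lab, colv in combos:
                labels.append(lab)
                cols.append(colv)
        return np.column_stack(cols), labels

    def encode(self, data: pd.DataFrame) -> np.ndarray:
        Xfull, _ = self._encode_full(data)
        return Xfull[:, self.keep]


def build_fixed_design(data: pd.DataFrame, terms: Sequence[str]):
    fd = FixedDesign(data, terms)
    return fd.X, fd.labels, fd.aliased


def _combined_codes(data: pd.DataFrame, cols: Sequence[str]):
    codes0, cats0 = _factor_codes(data, cols[0])
    labels = [str(c) for c in cats0]
    codes = codes0
    for c in cols[1:]:
        ci, cati = _factor_codes(data, c)
        labels = [f"{a}{_SEP}{b}" for a in labels for b in cati]
        codes = codes * len(cati) + ci
    # compress to observed levels
    observed = np.unique(codes)
    remap = -np.ones(len(labels), dtype=np.int64)
    remap[observed] = np.arange(len(observed))
    return remap[codes], [labels[k] for k in observed]


class _TermCols:
    """Column layout of one random term inside the global Z."""

    def __init__(self, term: RandomTerm, data: pd.DataFrame, offset: int):
        self.term = term
        gcodes, glabels = _combined_codes(data, term.group.split(":"))
        if term.structure == "IID":
            self.ncol = len(glabels)
            self.row_col = gcodes
            self.col_class = np.zeros(self.ncol, dtype=np.int64)
            self.class_labels = [None]
            self.n_par = 1
        elif term.structure == "DIAG":
            bcodes, blabels = _factor_codes(data, term.by)
            pair = gcodes * len(blabels) + bcodes
            observed = np.unique(pair)
            remap = {p: i for i, p in enumerate(observed)}
            self.ncol = len(observed)
            self.row_col = np.array([remap[p] for p in pair])
            self.col_class = np.array([p % len(blabels) for p in observed])
            self.class_labels = [str(b) for b in blabels]
            self.n_par = len(blabels)
        else:  # US2
            bcodes, blabels = _factor_codes(data, term.by)
            if len(blabels) != 2:
                raise ModelError(f"US2 stratifier {term.by!r} must have exactly 2 levels")
            self.ncol = 2 * len(glabels)
            self.row_col = gcodes * 2 + bcodes
            self.col_class = np.tile([0, 1], len(glabels))
            self.class_labels = [str(b) for b in blabels]
            self.n_par = 3
            self.pair0 = offset + np.arange(0, self.ncol, 2)
            self.pair1 = self.pair0 + 1
        self.offset = offset
        self.cols = offset + np.arange(self.ncol)
        self.group_labels = glabels


def _varcomp_names(term: RandomTerm, tc: _TermCols) -> list[str]:
    g = term.group
    if term.structure == "IID":
        return [f"sigma2:{g}"]
    if term.structure == "DIAG":
        return [f"sigma2:{g}|{term.by}={lab}" for lab in tc.class_labels]
    return [
        f"sigma2:{g}|{term.by}={tc.class_labels[0]}",
        f"sigma2:{g}|{term.by}={tc.class_labels[1]}",
        f"cov:{g}|{term.by}",
    ]


# ---------------------------------------------------------------------------
# the REML problem


class _Problem:
    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        if spec.response not in data.columns:
            raise ModelError(f"response column {spec.response!r} not in data")
        y_raw = pd.to_numeric(data[spec.response], errors="coerce").to_numpy(float)
        mask = np.isfinite(y_raw)
        if mask.sum() < len(y_raw):
            log.info("fit_lmm: excluding %d missing response rows", int((~mask).sum()))
        data = data.loc[mask].reset_index(drop=True)
        y = y_raw[mask]
        n = len(y)
        if n < 3:
            raise ModelError("too few observations")
        self.spec = spec
        self.n = n

        self.X, self.fixed_labels, self.aliased = build_fixed_design(data, spec.fixed)
        self.p = self.X.shape[1]
        if self.p >= n:
            raise ModelError("fixed design has as many columns as observations")

        # scaling: unit response variance, centered through the intercept
        self.center = float(np.mean(y))
        sd = float(np.std(y))
        self.scale = sd if sd > 1e-10 else 1.0
        self.y = (y - self.center) / self.scale

        # random terms
        self.terms: list[_TermCols] = []
        offset = 0
        for term in spec.random:
            tc = _TermCols(term, data, offset)
            offset += tc.ncol
            self.terms.append(tc)
        self.q = offset
        if self.q >= n:
            names = [t.term.group for t in self.terms]
            raise ModelError(
                f"random terms {names} have {self.q} levels for {n} observations; "
                "the model is not identifiable"
            )
        if self.q:
            rows = np.concatenate([np.arange(n)] * len(self.terms))
            cols = np.concatenate([t.offset + t.row_col for t in self.terms])
            self.Z = sp.coo_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(n, self.q)
            ).tocsr()
        else:
            self.Z = sp.csr_matrix((n, 0))

        # residual strata
        if spec.residual.structure == "IID":
            self.s_codes = np.zeros(n, dtype=np.int64)
            self.s_labels = [None]
        else:
            self.s_codes, raw = _combined_codes(data, spec.residual.by)
            pretty = []
            for lab in raw:
                parts = lab.split(_SEP)
                pretty.append(",".join(f"{c}={v}" for c, v in zip(spec.residual.by, parts)))
            self.s_labels = pretty
        self.n_strata = len(self.s_labels)
        self.s_counts = np.bincount(self.s_codes, minlength=self.n_strata).astype(float)

        # parameter layout
        self.par_names: list[str] = []
        self.term_slices = []
        pos = 0
        for tc in self.terms:
            self.par_names += _varcomp_names(tc.term, tc)
            self.term_slices.append(slice(pos, pos + tc.n_par))
            pos += tc.n_par
        self.res_slice = slice(pos, pos + self.n_strata)
        for lab in self.s_labels:
            self.par_names.append("sigma2:resid" if lab is None else f"sigma2:resid|{lab}")
        self.n_par = pos + self.n_strata

        self._precompute()

    # -- sufficient statistics and block structure --------------------------
    def _precompute(self):
        X, y, Z = self.X, self.y, self.Z
        self.XtX_s, self.Xty_s, self.yty_s = [], [], []
        self.ZtZ_s, self.ZtX_s, self.Zty_s, self.ZtZdiag_s = [], [], [], []
        for s in range(self.n_strata):
            idx = np.where(self.s_codes == s)[0]
            Xs, ys = X[idx], y[idx]
            self.XtX_s.append(Xs.T @ Xs)
            self.Xty_s.append(Xs.T @ ys)
            self.yty_s.append(float(ys @ ys))
            if self.q:
                Zs = Z[idx]
                ZtZ = (Zs.T @ Zs).tocsr()
                self.ZtZ_s.append(ZtZ)
                self.ZtX_s.append(np.asarray(Zs.T @ Xs))
                self.Zty_s.append(np.asarray(Zs.T @ ys).ravel())
                self.ZtZdiag_s.append(ZtZ.diagonal())
        if not self.q:
            return

        # connected components of the W sparsity pattern -> independent blocks
        pat = (Z.T @ Z).tolil()
        for tc in self.terms:
            if tc.term.structure == "US2":
                pat[tc.pair0, tc.pair1] = 1.0
                pat[tc.pair1, tc.pair0] = 1.0
        ncomp, comp = connected_components(pat.tocsr(), directed=False)
        order = np.argsort(comp, kind="stable")
        sizes = np.bincount(comp)
        self.block_groups = []  # (idx_array (nb, b), )
        csr_ZtZ = [m.tocsr() for m in self.ZtZ_s]
        for b in np.unique(sizes):
            blocks = np.where(sizes == b)[0]
            idx = np.empty((len(blocks), b), dtype=np.int64)
            ptr = np.searchsorted(comp[order], blocks)
            for i, blk in enumerate(blocks):
                idx[i] = np.sort(order[ptr[i] : ptr[i] + b])
            ztz_blocks = []
            for m in csr_ZtZ:
                arr = np.empty((len(blocks), b, b))
                for i in range(len(blocks)):
                    sub = m[idx[i]][:, idx[i]]
                    arr[i] = sub.toarray()
                ztz_blocks.append(arr)
            self.block_groups.append({"idx": idx, "ztz": ztz_blocks})
        # Winv sparse assembly pattern
        rows = np.concatenate(
            [np.repeat(g["idx"], g["idx"].shape[1], axis=1).ravel() for g in self.block_groups]
        )
        colsr = np.concatenate(
            [np.tile(g["idx"], (1, g["idx"].shape[1])).ravel() for g in self.block_groups]
        )
        self._winv_rows, self._winv_cols = rows, colsr
        # per-column positions inside their block, for Ginv filling
        self.colpos = np.empty(self.q, dtype=np.int64)
        self.colgroup = np.empty(self.q, dtype=np.int64)  # which size-group
        self.colblock = np.empty(self.q, dtype=np.int64)  # block index within group
        for gi, g in enumerate(self.block_groups):
            idx = g["idx"]
            nb, b = idx.shape
            self.colgroup[idx.ravel()] = gi
            self.colblock[idx.ravel()] = np.repeat(np.arange(nb), b)
            self.colpos[idx.ravel()] = np.tile(np.arange(b), nb)

    # -- parameter transforms ------------------------------------------------
    def _unpack(self, theta):
        """Return per-column Ginv diagonal, US2 off-diagonal info, logdetG, rinv."""
        ginv_diag = np.empty(self.q)
        logdetG = 0.0
        us2 = []  # (tc, G2, Ginv2)
        for tc, sl in zip(self.terms, self.term_slices):
            t = theta[sl]
            if tc.term.structure in ("IID", "DIAG"):
                v = np.exp(t)
                ginv_diag[tc.cols] = 1.0 / v[tc.col_class]
                logdetG += float(np.bincount(tc.col_class, minlength=tc.n_par) @ t)
            else:
                a, b, c = t
                l11, l22 = np.exp(a), np.exp(b)
                G2 = np.array([[l11**2, l11 * c], [l11 * c, c**2 + l22**2]])
                det = (l11 * l22) ** 2
                Ginv2 = np.array([[G2[1, 1], -G2[0, 1]], [-G2[0, 1], G2[0, 0]]]) / det
                ginv_diag[tc.cols[tc.col_class == 0]] = Ginv2[0, 0]
                ginv_diag[tc.cols[tc.col_class == 1]] = Ginv2[1, 1]
                logdetG += len(tc.group_labels) * 2 * (a + b)
                us2.append((tc, G2, Ginv2))
        rvar = np.exp(theta[self.res_slice])
        return ginv_diag, us2, logdetG, rvar

    def _w_blocks(self, ginv_diag, us2, rinv):
        out = []
        for gi, g in enumerate(self.block_groups):
            idx = g["idx"]
            nb, b = idx.shape
            W = np.zeros((nb, b, b))
            for s in range(self.n_strata):
                W += rinv[s] * g["ztz"][s]
            d = ginv_diag[idx]  # (nb, b)
            bi = np.arange(b)
            W[:, bi, bi] += d
            out.append(W)
        # US2 off-diagonal Ginv entries
        for tc, G2, Ginv2 in us2:
            gi = self.colgroup[tc.pair0]
            bi = self.colblock[tc.pair0]
            p0 = self.colpos[tc.pair0]
            p1 = self.colpos[tc.pair1]
            for gidx in np.unique(gi):
                m = gi == gidx
                out[gidx][bi[m], p0[m], p1[m]] += Ginv2[0, 1]
                out[gidx][bi[m], p1[m], p0[m]] += Ginv2[0, 1]
        return out

    def _solve_blocks(self, Wb):
        """Batched Cholesky: returns (logdetW, Winv_blocks) or None if not PD."""
        logdet = 0.0
        Winv = []
        for W in Wb:
            try:
                L = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return None
            d = np.diagonal(L, axis1=1, axis2=2)
            logdet += 2.0 * float(np.log(d).sum())
            Winv.append(np.linalg.inv(W))
        return logdet, Winv

    def _apply_winv(self, Winv, M):
        """Winv @ M for dense M (q x k), via batched block multiplication."""
        out = np.empty_like(M)
        for g, Wi in zip(self.block_groups, Winv):
            idx = g["idx"]
            out[idx.ravel()] = (Wi @ M[idx]).reshape(-1, M.shape[1])
        return out

    def _winv_sparse(self, Winv):
        data = np.concatenate([Wi.ravel() for Wi in Winv])
        return sp.coo_matrix(
            (data, (self._winv_rows, self._winv_cols)), shape=(self.q, self.q)
        ).tocsr()

    # -- likelihood ----------------------------------------------------------
    def _core(self, theta):
        """Shared pieces for loglik and gradient.  Returns None if W not PD."""
        ginv_diag, us2, logdetG, rvar = self._unpack(theta)
        rinv = 1.0 / rvar
        Sxx = sum(r * m for r, m in zip(rinv, self.XtX_s))
        sxy = sum(r * m for r, m in zip(rinv, self.Xty_s))
        syy = float(sum(r * m for r, m in zip(rinv, self.yty_s)))
        logdetR = float(self.s_counts @ np.log(rvar))
        if self.q:
            Wb = self._w_blocks(ginv_diag, us2, rinv)
            solved = self._solve_blocks(Wb)
            if solved is None:
                return None
            logdetW, Winv = solved
            Cx = sum(r * m for r, m in zip(rinv, self.ZtX_s))
            cy = sum(r * m for r, m in zip(rinv, self.Zty_s))
            U = self._apply_winv(Winv, Cx)
            w = self._apply_winv(Winv, cy[:, None]).ravel()
            B = Sxx - Cx.T @ U
            bxy = sxy - Cx.T @ w
            yVy = syy - float(cy @ w)
        else:
            Winv, U, w, Cx, cy, logdetW = None, None, None, None, None, 0.0
            B, bxy, yVy = Sxx, sxy, syy
        B = 0.5 * (B + B.T)
        try:
            choB = sla.cho_factor(B)
        except sla.LinAlgError:
            return None
        logdetB = 2.0 * float(np.log(np.diag(choB[0])).sum())
        beta = sla.cho_solve(choB, bxy)
        yPy = yVy - float(bxy @ beta)
        ll = -0.5 * (
            (self.n - self.p) * np.log(2 * np.pi) + logdetR + logdetG + logdetW + logdetB + yPy
        )
        return dict(
            ll=ll, beta=beta, choB=choB, Winv=Winv, U=U, w=w, Cx=Cx, cy=cy,
            rinv=rinv, rvar=rvar, us2=us2, ginv_diag=ginv_diag,
        )

    def loglik(self, theta) -> float:
        core = self._core(theta)
        return -np.inf if core is None else core["ll"]

    def loglik_grad(self, theta):
        core = self._core(theta)
        if core is None:
            return -np.inf, np.zeros(self.n_par)
        beta, choB, rinv, rvar = core["beta"], core["choB"], core["rinv"], core["rvar"]
        Winv, U, Cx = core["Winv"], core["U"], core["Cx"]
        grad = np.zeros(self.n_par)
        rinv_row = rinv[self.s_codes]
        e = self.y - self.X @ beta
        Binv = sla.cho_solve(choB, np.eye(self.p))
        if self.q:
            Wsp = self._winv_sparse(Winv)
            C = sum(r * m for r, m in zip(rinv, self.ZtZ_s))
            Cdiag = sum(r * d for r, d in zip(rinv, self.ZtZdiag_s))
            # v = P y = V^-1 (y - X beta)
            zre = np.asarray(self.Z.T @ (rinv_row * e)).ravel()
            v = rinv_row * e - rinv_row * np.asarray(self.Z @ (Wsp @ zre)).ravel()
            t = np.asarray(self.Z.T @ v).ravel()
            M = (Wsp @ C).tocsc()  # Winv C
            Ccsc = C.tocsc()
            diagCWC = np.asarray(Ccsc.multiply(M).sum(axis=0)).ravel()
            Vx = Cx - np.asarray(Ccsc @ U)  # Z' V^-1 X
            qf = np.einsum("ip,pq,iq->i", Vx, Binv, Vx)
            diagT = Cdiag - diagCWC - qf
        else:
            v = rinv_row * e
        for tc, sl in zip(self.terms, self.term_slices):
            th = theta[sl]
            if tc.term.structure in ("IID", "DIAG"):
                var = np.exp(th)
                trs = np.bincount(
                    tc.col_class, weights=diagT[tc.cols], minlength=tc.n_par
                )
                quad = np.bincount(
                    tc.col_class, weights=t[tc.cols] ** 2, minlength=tc.n_par
                )
                grad[sl] = -0.5 * var * (trs - quad)
            else:
                a, b, c = th
                l11, l22 = np.exp(a), np.exp(b)
                j0, j1 = tc.pair0, tc.pair1
                offCWC = np.asarray(Ccsc[:, j0].multiply(M[:, j1]).sum(axis=0)).ravel()
                offC = np.asarray(C[j0, j1]).ravel() if C[j0, j1].size else np.zeros(len(j0))
                offqf = np.einsum("ip,pq,iq->i", Vx[j0], Binv, Vx[j1])
                T11 = float(diagT[j0].sum())
                T22 = float(diagT[j1].sum())
                T12 = float((offC - offCWC - offqf).sum())
                Q11 = float((t[j0] ** 2).sum())
                Q22 = float((t[j1] ** 2).sum())
                Q12 = float((t[j0] * t[j1]).sum())
                for k, dG in enumerate(
                    (
                        np.array([[2 * l11**2, c * l11], [c * l11, 0.0]]),
                        np.array([[0.0, 0.0], [0.0, 2 * l22**2]]),
                        np.array([[0.0, l11], [l11, 2 * c]]),
                    )
                ):
                    tr = dG[0, 0] * (T11 - Q11) + 2 * dG[0, 1] * (T12 - Q12) + dG[1, 1] * (
                        T22 - Q22
                    )
                    grad[sl][k] = -0.5 * tr
        # residual strata: sum_{i in s} a_i' Binv a_i = rinv_s^2 tr(Binv M_s)
        # with M_s = (X - Z U)' (X - Z U) restricted to stratum s, assembled
        # from the precomputed per-stratum cross-products
        for s in range(self.n_strata):
            ins = self.s_codes == s
            trV = self.s_counts[s] * rinv[s]
            if self.q:
                trV -= rinv[s] ** 2 * float(Wsp.multiply(self.ZtZ_s[s]).sum())
                ZU = np.asarray(self.ZtZ_s[s] @ U)
                Ms = (
                    self.XtX_s[s]
                    - self.ZtX_s[s].T @ U
                    - U.T @ self.ZtX_s[s]
                    + U.T @ ZU
                )
            else:
                Ms = self.XtX_s[s]
            trP = trV - rinv[s] ** 2 * float((Binv * Ms).sum())
            quad = float((v[ins] ** 2).sum())
            grad[self.res_slice][s] = -0.5 * rvar[s] * (trP - quad)
        return core["ll"], grad

    # -- optimisation --------------------------------------------------------
    def start_values(self):
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        rss = float(np.sum((self.y - self.X @ beta0) ** 2))
        resvar = max(rss / max(self.n - self.p, 1), 1e-6)
        nt = max(len(self.terms), 1)
        base = np.empty(self.n_par)
        for tc, sl in zip(self.terms, self.term_slices):
            lv = np.log(0.5 * resvar / nt)
            if tc.term.structure == "US2":
                base[sl] = [0.5 * lv, 0.5 * lv, 0.0]
            else:
                base[sl] = lv
        base[self.res_slice] = np.log(0.5 * resvar)
        starts = [base]
        for sgn in (1.0, -1.0):
            pert = base.copy()
            for tc, sl in zip(self.terms, self.term_slices):
                if tc.term.structure == "US2":
                    pert[sl.start : sl.start + 2] += sgn * 0.5 * np.log(4.0)
                else:
                    pert[sl] += sgn * np.log(4.0)
            pert[self.res_slice] -= sgn * np.log(2.0)
            starts.append(pert)
        return starts

    def bounds(self):
        bnds = []
        for tc, sl in zip(self.terms, self.term_slices):
            if tc.term.structure == "US2":
                bnds += [(_LOGV_LB / 2, _LOGV_UB / 2)] * 2 + [(-400.0, 400.0)]
            else:
                bnds += [(_LOGV_LB, _LOGV_UB)] * tc.n_par
        bnds += [(_LOGV_LB, _LOGV_UB)] * self.n_strata
        return bnds

    def optimize(self, n_starts=3, max_iter=500, tol=1e-10):
        def neg(theta):
            ll, g = self.loglik_grad(theta)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(theta)
            return -ll, -g

        best = None
        bounds = self.bounds()
        for theta0 in self.start_values()[:n_starts]:
            res = minimize(
                neg,
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        # L-BFGS-B reports ABNORMAL when the line search stalls at machine
        # precision; accept the optimum if the projected gradient is tiny
        if not best.success:
            g = np.asarray(best.jac, float).copy()
            at_lb = best.x <= np.array([b[0] for b in bounds]) + 1e-12
            at_ub = best.x >= np.array([b[1] for b in bounds]) - 1e-12
            g[at_lb & (g > 0)] = 0.0
            g[at_ub & (g < 0)] = 0.0
            if np.max(np.abs(g)) < max(1e-2, 1e-5 * abs(best.fun)):
                best.success = True
        return best


def fit_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_starts: int = 3,
    max_iter: int = 500,
) -> REMLFit:
    """Fit a mixed model by REML.

    Returns a :class:`REMLFit` with variance components on the original trait
    scale, GLS fixed-effect estimates with standard errors, and the restricted
    log-likelihood.  Non-convergence is flagged on the fit, never silent.
    """
    prob = _Problem(spec, data)
    res = prob.optimize(n_starts=n_starts, max_iter=max_iter)
    theta = res.x
    core = prob._core(theta)
    if core is None:  # pragma: no cover - PD failure at the optimum
        raise ModelError("likelihood not evaluable at the optimum")
    c2 = prob.scale**2

    varcomp: dict[str, float] = {}
    at_bound = False
    for tc, sl in zip(prob.terms, prob.term_slices):
        names = _varcomp_names(tc.term, tc)
        th = theta[sl]
        if tc.term.structure in ("IID", "DIAG"):
            for name, lv in zip(names, th):
                v = float(np.exp(lv))
                if v < _ZERO_VAR:
                    v, bound = 0.0, True
                else:
                    bound = lv > _LOGV_UB - 1e-6
                at_bound |= bound
                varcomp[name] = v * c2
        else:
            a, b, cpar = th
            l11, l22 = np.exp(a), np.exp(b)
            v1, v2 = l11**2, cpar**2 + l22**2
            cov = l11 * cpar
            v1 = 0.0 if v1 < _ZERO_VAR else v1
            v2 = 0.0 if v2 < _ZERO_VAR else v2
            varcomp[names[0]] = v1 * c2
            varcomp[names[1]] = v2 * c2
            varcomp[names[2]] = cov * c2
            denom = np.sqrt(v1 * v2)
            corr = cov / denom if denom > 0 else np.nan
            if np.isfinite(corr) and abs(corr) > 0.9999:
                at_bound = True
            varcomp[names[2].replace("cov:", "corr:", 1)] = corr
    for s, lab in enumerate(prob.s_labels):
        name = "sigma2:resid" if lab is None else f"sigma2:resid|{lab}"
        v = float(np.exp(theta[prob.res_slice][s]))
        varcomp[name] = (0.0 if v < _ZERO_VAR else v) * c2

    beta = core["beta"] * prob.scale
    Binv = sla.cho_solve(core["choB"], np.eye(prob.p))
    se = np.sqrt(np.diag(Binv)) * prob.scale
    if "Intercept" in prob.fixed_labels:
        beta[prob.fixed_labels.index("Intercept")] += prob.center
    fx = pd.DataFrame({"effect": prob.fixed_labels, "estimate": beta, "se": se})
    fx["aliased"] = False
    if prob.aliased:
        fx = pd.concat(
            [
                fx,
                pd.DataFrame(
                    {
                        "effect": prob.aliased,
                        "estimate": np.nan,
                        "se": np.nan,
                        "aliased": True,
                    }
                ),
            ],
            ignore_index=True,
        )

    loglik = float(core["ll"] - (prob.n - prob.p) * np.log(prob.scale))
    converged = bool(res.success)
    if not converged:
        log.warning("fit_lmm: optimizer did not converge (%s)", res.message)
    ys = np.sort(prob.y)
    y_key = (prob.n, round(float(ys.sum()), 6), round(float(ys @ ys), 6))
    return REMLFit(
        spec=spec,
        fixed_estimates=fx,
        varcomp=varcomp,
        loglik=loglik,
        converged=converged,
        n_obs=prob.n,
        n_fixed=prob.p,
        at_bound=at_bound,
        n_iter=int(res.nit),
        aliased=tuple(prob.aliased),
        _y_key=y_key,
    )


def reml_loglik(spec: ModelSpec, data: pd.DataFrame, varcomp: dict[str, float]) -> float:
    """Evaluate the restricted log-likelihood at given variance components.

    ``varcomp`` uses the same names a fit reports (the derived ``corr:`` entry
    is ignored).  Used to verify that a fit's reported loglik is reproducible.
    """
    prob = _Problem(spec, data)
    c2 = prob.scale**2
    theta = np.empty(prob.n_par)
    for tc, sl in zip(prob.terms, prob.term_slices):
        names = _varcomp_names(tc.term, tc)
        if tc.term.structure in ("IID", "DIAG"):
            theta[sl] = [np.log(max(varcomp[n] / c2, 1e-300)) for n in names]
        else:
            v1 = varcomp[names[0]] / c2
            v2 = varcomp[names[1]] / c2
            cov = varcomp[names[2]] / c2
            l11 = np.sqrt(max(v1, 1e-300))
            cpar = cov / l11
            l22 = np.sqrt(max(v2 - cpar**2, 1e-300))
            theta[sl] = [np.log(l11), np.log(l22), cpar]
    for s, lab in enumerate(prob.s_labels):
        name = "sigma2:resid" if lab is None else f"sigma2:resid|{lab}"
        theta[prob.res_slice][s] = np.log(max(varcomp[name] / c2, 1e-300))
    return float(prob.loglik(theta) - (prob.n - prob.p) * np.log(prob.scale))


def lrt(full: REMLFit, reduced: REMLFit, df: int) -> tuple[float, float]:
    """REML likelihood-ratio test of nested random structures.

    Both fits must be on the same data with the same fixed-effect structure
    (a REML-valid comparison); otherwise the comparison is refused.
    """
    if df < 1:
        raise ValueError("df must be a positive integer")
    lf = set(full.fixed_estimates["effect"])
    lr = set(reduced.fixed_estimates["effect"])
    if lf != lr:
        raise ModelError(
            "LRT refused: fits have different fixed-effect structures "
            f"({sorted(lf ^ lr)}); REML log-likelihoods are not comparable"
        )
    if full._y_key != reduced._y_key:
        raise ModelError("LRT refused: fits are not on the same response data")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, float(chi2.sf(stat, df))


def wald_fixed(fit: REMLFit, df_method: str = "residual") -> pd.DataFrame:
    """Wald t-tests for each fixed effect.

    Degrees of freedom use the residual approximation n_obs - rank(X)
    (documented approximation; exact Kenward-Roger is out of scope).  Aliased
    effects are reported without a test.
    """
    if df_method not in ("residual", "containment"):
        raise ValueError(f"unknown df_method {df_method!r}")
    out = fit.fixed_estimates.copy()
    df = float(fit.n_obs - fit.n_fixed)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["t"] = out["estimate"] / out["se"]
    out["df"] = np.where(out["aliased"], np.nan, df)
    out["p"] = 2.0 * t_dist.sf(np.abs(out["t"]), df)
    out.loc[out["aliased"], ["t", "p"]] = np.nan
    return out
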