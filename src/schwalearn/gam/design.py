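"""Design-matrix construction for penalized-spline models.

Each :class:`SmoothTerm` turns into a block of columns of the model matrix
plus one or two quadratic penalties; by-factor smooths replicate the block
per factor level with a shared smoothing parameter per penalty direction;
grouped factor smooths build per-level spline deviations with a shared
wiggliness penalty and a shared ridge penalty (the penalized-null-space
analogue of a random factor smooth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..errors import ConfigError, DomainError
from .basis import (bspline_basis, difference_penalty, greville_abscissae,
                    row_kron, sum_to_zero_constraint)

KINDS = ("univariate", "tensor", "partial_tensor", "group_smooth")

_DEFAULT_K = {"univariate": (10,), "tensor": (5, 5),
              "partial_tensor": (5, 5), "group_smooth": (5,)}


@dataclass
class SmoothTerm:
    kind: str
    covariates: Tuple[str, ...]
    by: Optional[str] = None
    k: Tuple[int, ...] = ()
    penalty_order: int = 2
    group: Optional[str] = None  # grouping factor for group_smooth
    degree: int = 3
    name: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown smooth kind {self.kind!r}")
        self.covariates = tuple(self.covariates)
        if not self.k:
            self.k = _DEFAULT_K[self.kind]
        self.k = tuple(self.k)
        n_cov = 2 if self.kind in ("tensor", "partial_tensor") else 1
        if len(self.covariates) != n_cov or len(self.k) != n_cov:
            raise ConfigError(f"{self.kind} smooth needs {n_cov} covariate(s) "
                              f"and basis sizes, got {self.covariates}/{self.k}")
        for ki in self.k:
            if ki < self.penalty_order + 1:
                raise ConfigError(
                    f"basis size {ki} must be >= penalty_order + 1")
        if self.kind == "group_smooth" and self.group is None:
            raise ConfigError("group_smooth requires a grouping factor")
        if not self.name:
            parts = [self.kind, "_".join(self.covariates)]
            if self.group:
                parts.append(f"g={self.group}")
            if self.by:
                parts.append(f"by={self.by}")
            self.name = ":".join(parts)


@dataclass
class _FittedTerm:
    term: SmoothTerm
    sl: slice
    domains: List[Tuple[float, float]]
    by_levels: List = field(default_factory=list)
    group_levels: List = field(default_factory=list)
    Z: Optional[np.ndarray] = None          # constraint for univariate/tensor
    Z1: Optional[np.ndarray] = None         # marginal constraints for ti
    Z2: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None          # ti orthogonalization coefficients


class DesignBuilder:
    """Builds (and rebuilds, for prediction) the full model matrix.

    ``factors`` become treatment-coded fixed effects after an intercept.
    Penalties are exposed as a list of ``(slice, S, lambda_index, name)``.
    """

    def __init__(self, terms: Sequence[SmoothTerm], factors: Sequence[str] = ()):
        self.terms = list(terms)
        self.factors = list(factors)

    # -- fitting -----------------------------------------------------------

    def fit(self, df: pd.DataFrame) -> "DesignBuilder":
        self.factor_levels_: Dict[str, List] = {
            f: sorted(df[f].astype(str).unique()) for f in self.factors
        }
        blocks = [np.ones((len(df), 1))]
        col = 1
        self.fixed_slices_: Dict[str, slice] = {"intercept": slice(0, 1)}
        for f in self.factors:
            levels = self.factor_levels_[f]
            dummies = np.column_stack([
                (df[f].astype(str) == lev).to_numpy(float) for lev in levels[1:]
            ]) if len(levels) > 1 else np.zeros((len(df), 0))
            blocks.append(dummies)
            self.fixed_slices_[f] = slice(col, col + dummies.shape[1])
            col += dummies.shape[1]

        self.fitted_terms_: List[_FittedTerm] = []
        self.penalties_: List[Tuple[slice, np.ndarray, int, str]] = []
        lam_idx = 0
        for term in self.terms:
            block, pens, ft = self._build_term(df, term, fitting=True)
            sl = slice(col, col + block.shape[1])
            ft.sl = sl
            blocks.append(block)
            for S, tag in pens:
                self.penalties_.append((sl, S, lam_idx, f"{term.name}:{tag}"))
                lam_idx += 1
            self.fitted_terms_.append(ft)
            col += block.shape[1]
        self.n_lambda_ = lam_idx
        self.p_ = col
        self.X_ = np.hstack(blocks)
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(df), 1))]
        for f in self.factors:
            levels = self.factor_levels_[f]
            if len(levels) > 1:
                blocks.append(np.column_stack([
                    (df[f].astype(str) == lev).to_numpy(float)
                    for lev in levels[1:]
                ]))
        for ft in self.fitted_terms_:
            block, _, _ = self._build_term(df, ft.term, fitting=False, fitted=ft)
            blocks.append(block)
        return np.hstack(blocks)

    # -- per-term construction --------------------------------------------

    @staticmethod
    def _pen(k, degree, domain, order):
        return difference_penalty(k, order, greville_abscissae(k, degree, domain))

    def _marginal(self, df, cov, k, degree, domain):
        x = df[cov].to_numpy(float)
        if domain is None:
            domain = (float(x.min()), float(x.max()))
        return bspline_basis(x, k, degree, domain), domain

    def _by_expand(self, df, block, pens, term, levels):
        """Replicate a functional block per by-level (shared lambdas)."""
        if term.by is None:
            return block, pens, []
        vals = df[term.by].astype(str)
        if levels is None:
            levels = sorted(vals.unique())
        cols = []
        for lev in levels:
            ind = (vals == lev).to_numpy(float)[:, None]
            cols.append(block * ind)
        big = np.hstack(cols)
        L = len(levels)
        pens = [(np.kron(np.eye(L), S), tag) for S, tag in pens]
        return big, pens, list(levels)

    def _build_term(self, df, term: SmoothTerm, fitting: bool,
                    fitted: _FittedTerm | None = None):
        ft = fitted if fitted is not None else _FittedTerm(term, slice(0, 0), [])
        if term.kind == "univariate":
            dom = None if fitting else ft.domains[0]
            B, dom = self._marginal(df, term.covariates[0], term.k[0],
                                    term.degree, dom)
            if fitting:
                ft.domains = [dom]
                ft.Z = sum_to_zero_constraint(B)
            F = B @ ft.Z
            S = ft.Z.T @ self._pen(term.k[0], term.degree, dom,
                                   term.penalty_order) @ ft.Z
            pens = [(S, "diff")]
        elif term.kind == "tensor":
            dom1 = None if fitting else ft.domains[0]
            dom2 = None if fitting else ft.domains[1]
            B1, dom1 = self._marginal(df, term.covariates[0], term.k[0],
                                      term.degree, dom1)
            B2, dom2 = self._marginal(df, term.covariates[1], term.k[1],
                                      term.degree, dom2)
            T = row_kron(B1, B2)
            if fitting:
                ft.domains = [dom1, dom2]
                ft.Z = sum_to_zero_constraint(T)
            F = T @ ft.Z
            S1 = self._pen(term.k[0], term.degree, dom1, term.penalty_order)
            S2 = self._pen(term.k[1], term.degree, dom2, term.penalty_order)
            pens = [
                (ft.Z.T @ np.kron(S1, np.eye(term.k[1])) @ ft.Z, "diff1"),
                (ft.Z.T @ np.kron(np.eye(term.k[0]), S2) @ ft.Z, "diff2"),
            ]
        elif term.kind == "partial_tensor":
            dom1 = None if fitting else ft.domains[0]
            dom2 = None if fitting else ft.domains[1]
            B1, dom1 = self._marginal(df, term.covariates[0], term.k[0],
                                      term.degree, dom1)
            B2, dom2 = self._marginal(df, term.covariates[1], term.k[1],
                                      term.degree, dom2)
            if fitting:
                ft.domains = [dom1, dom2]
                ft.Z1 = sum_to_zero_constraint(B1)
                ft.Z2 = sum_to_zero_constraint(B2)
            B1c, B2c = B1 @ ft.Z1, B2 @ ft.Z2
            T = row_kron(B1c, B2c)
            M = np.hstack([B1c, B2c])
            if fitting:
                ft.A, *_ = np.linalg.lstsq(M, T, rcond=None)
            F = T - M @ ft.A
            S1c = ft.Z1.T @ self._pen(term.k[0], term.degree, dom1,
                                      term.penalty_order) @ ft.Z1
            S2c = ft.Z2.T @ self._pen(term.k[1], term.degree, dom2,
                                      term.penalty_order) @ ft.Z2
            pens = [
                (np.kron(S1c, np.eye(B2c.shape[1])), "diff1"),
                (np.kron(np.eye(B1c.shape[1]), S2c), "diff2"),
            ]
        elif term.kind == "group_smooth":
            dom = None if fitting else ft.domains[0]
            B, dom = self._marginal(df, term.covariates[0], term.k[0],
                                    term.degree, dom)
            if fitting:
                ft.domains = [dom]
            keys = df[term.group].astype(str)
            if term.by is not None:
                keys = keys + "\x1f" + df[term.by].astype(str)
            if fitting:
                ft.group_levels = sorted(keys.unique())
            cols = []
            for lev in ft.group_levels:
                ind = (keys == lev).to_numpy(float)[:, None]
                cols.append(B * ind)
            F = np.hstack(cols)
            L = len(ft.group_levels)
            k = term.k[0]
            wiggle = np.kron(np.eye(L), self._pen(k, term.degree, dom, 1))
            ridge = np.eye(L * k)
            return F, [(wiggle, "wiggle"), (ridge, "ridge")], ft
        else:  # pragma: no cover
            raise DomainError(f"unknown term kind {term.kind}")

        levels = None if fitting else (ft.by_levels or None)
        F, pens, by_levels = self._by_expand(df, F, pens, term, levels)
        if fitting:
            ft.by_levels = by_levels
        return F, pens, ft
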