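"""Conditional independence tests for mixed continuous/categorical data.

Test family by variable types:

* continuous-continuous with continuous conditioning set: Fisher-z test of
  the partial correlation;
* any categorical involvement with at least one continuous member of the
  pair: nested linear models (regress the continuous member on Z vs
  Z + other), F-test on the added terms;
* both members categorical: nested logistic (binary) or multinomial
  likelihood-ratio deviance test.

Results are cached per (pair, conditioning set), so repeated queries across
an alpha grid cost one computation.
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CITester", "OracleCITester"]

log = logging.getLogger(__name__)


class CITester:
    def __init__(self, data: pd.DataFrame, types: Optional[Dict[str, str]] = None,
                 min_residual_dof: int = 5):
        self.nodes = list(data.columns)
        if types is None:
            types = {c: "continuous" for c in self.nodes}
        self.types = dict(types)
        self.n = len(data)
        self.min_residual_dof = min_residual_dof
        self._cache: Dict[Tuple[str, str, FrozenSet[str]], float] = {}
        self.skipped: list = []

        self._cols: Dict[str, np.ndarray] = {}      # numeric column (standardized)
        self._dummies: Dict[str, np.ndarray] = {}   # predictor encoding
        for c in self.nodes:
            v = data[c]
            if self.types.get(c, "continuous") == "continuous":
                x = v.to_numpy(dtype=float)
                sd = x.std()
                x = (x - x.mean()) / (sd if sd > 0 else 1.0)
                self._cols[c] = x
                self._dummies[c] = x[:, None]
            else:
                codes, levels = pd.factorize(v)
                if len(levels) < 2:
                    raise ValueError(f"categorical variable {c!r} has < 2 levels")
                self._cols[c] = codes.astype(float)
                # reference-coded indicators
                dm = np.zeros((self.n, len(levels) - 1))
                for j in range(1, len(levels)):
                    dm[:, j - 1] = (codes == j).astype(float)
                self._dummies[c] = dm
        cont = [c for c in self.nodes
                if self.types.get(c, "continuous") == "continuous"]
        self._cont_idx = {c: i for i, c in enumerate(cont)}
        if cont:
            mat = np.column_stack([self._cols[c] for c in cont])
            self._corr = np.corrcoef(mat, rowvar=False)
            if self._corr.ndim == 0:
                self._corr = self._corr.reshape(1, 1)

    # -- public API ---------------------------------------------------------

    def pvalue(self, x: str, y: str, Z: Iterable[str] = ()) -> float:
        Z = frozenset(Z)
        if x == y or x in Z or y in Z:
            raise ValueError("x, y must be distinct and not in Z")
        key = (x, y) if x < y else (y, x)
        cached = self._cache.get((key[0], key[1], Z))
        if cached is not None:
            return cached
        p = self._compute(x, y, sorted(Z))
        self._cache[(key[0], key[1], Z)] = p
        return p

    def independent(self, x: str, y: str, Z: Iterable[str], alpha: float) -> bool:
        return self.pvalue(x, y, Z) >= alpha

    # -- internals ----------------------------------------------------------

    def _is_cont(self, v: str) -> bool:
        return self.types.get(v, "continuous") == "continuous"

    def _compute(self, x: str, y: str, Z: Sequence[str]) -> float:
        all_cont = self._is_cont(x) and self._is_cont(y) and \
            all(self._is_cont(z) for z in Z)
        n_params = 1 + len(Z) + 1
        if self.n - n_params < self.min_residual_dof:
            # too few rows: conservatively declare dependence
            self.skipped.append((x, y, tuple(Z)))
            log.debug("ci_test skipped (n too small): %s vs %s | %s", x, y, Z)
            return 0.0
        if all_cont:
            return self._fisher_z(x, y, Z)
        if self._is_cont(x) or self._is_cont(y):
            resp, other = (x, y) if self._is_cont(x) else (y, x)
            return self._linear_lr(resp, other, Z)
        return self._logistic_lr(x, y, Z)

    def _fisher_z(self, x: str, y: str, Z: Sequence[str]) -> float:
        idx = [self._cont_idx[x], self._cont_idx[y]] + \
              [self._cont_idx[z] for z in Z]
        sub = self._corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            return 0.0
        denom = np.sqrt(prec[0, 0] * prec[1, 1])
        r = -prec[0, 1] / denom if denom > 0 else 0.0
        r = float(np.clip(r, -0.9999999, 0.9999999))
        dof = self.n - len(Z) - 3
        if dof <= 0:
            self.skipped.append((x, y, tuple(Z)))
            return 0.0
        zstat = np.sqrt(dof) * np.arctanh(r)
        return float(2.0 * stats.norm.sf(abs(zstat)))

    def _design(self, cols: Sequence[str]) -> np.ndarray:
        parts = [np.ones((self.n, 1))]
        parts.extend(self._dummies[c] for c in cols)
        return np.hstack(parts)

    def _linear_lr(self, resp: str, other: str, Z: Sequence[str]) -> float:
        yv = self._cols[resp]
        X0 = self._design(Z)
        X1 = np.hstack([X0, self._dummies[other]])
        rss0 = _rss(X0, yv)
        rss1 = _rss(X1, yv)
        df_add = X1.shape[1] - X0.shape[1]
        df_res = self.n - X1.shape[1]
        if df_res <= 0 or rss1 <= 0:
            return 0.0
        f = max(rss0 - rss1, 0.0) / df_add / (rss1 / df_res)
        return float(stats.f.sf(f, df_add, df_res))

    def _logistic_lr(self, x: str, y: str, Z: Sequence[str]) -> float:
        from ..differential import _logit_fit

        codes = self._cols[x]
        levels = np.unique(codes)
        X0 = self._design(Z)
        X1 = np.hstack([X0, self._dummies[y]])
        df_add = (X1.shape[1] - X0.shape[1]) * (len(levels) - 1)

        def deviance(X: np.ndarray) -> float:
            if len(levels) == 2:
                yv = (codes == levels[1]).astype(float)
                beta, _, _, _ = _logit_fit(X, yv)
                eta = np.clip(X @ beta, -30, 30)
                mu = 1.0 / (1.0 + np.exp(-eta))
                mu = np.clip(mu, 1e-12, 1 - 1e-12)
                return -2.0 * float(np.sum(yv * np.log(mu)
                                           + (1 - yv) * np.log(1 - mu)))
            # multinomial via one-vs-rest deviance sum (approximate)
            dev = 0.0
            for lev in levels[1:]:
                yv = (codes == lev).astype(float)
                beta, _, _, _ = _logit_fit(X, yv)
                eta = np.clip(X @ beta, -30, 30)
                mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
                dev += -2.0 * float(np.sum(yv * np.log(mu)
                                           + (1 - yv) * np.log(1 - mu)))
            return dev

        lr = max(deviance(X0) - deviance(X1), 0.0)
        return float(stats.chi2.sf(lr, df_add))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


class OracleCITester:
    """d-separation oracle over a known DAG (for exact-recovery checks)."""

    def __init__(self, dag):
        import networkx as nx
        self.dag = dag
        self.nodes = list(dag.nodes)
        self.n = np.inf
        self._nx = nx
        self._cache: Dict = {}

    def pvalue(self, x: str, y: str, Z: Iterable[str] = ()) -> float:
        Z = frozenset(Z)
        key = (min(x, y), max(x, y), Z)
        if key not in self._cache:
            sep = self._nx.is_d_separator(self.dag, {x}, {y}, set(Z))
            self._cache[key] = 1.0 if sep else 0.0
        return self._cache[key]

    def independent(self, x: str, y: str, Z: Iterable[str], alpha: float) -> bool:
        return self.pvalue(x, y, Z) >= alpha
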