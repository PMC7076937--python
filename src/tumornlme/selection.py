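"""Information criteria and Akaike-style model weights.

Conventions (recorded in every emitted table's metadata):

- AIC  = -2LL + 2k
- AICc = AIC + 2k(k+1)/(n - k - 1),  n = number of observations
- BIC  = -2LL + k ln(m), with m = number of subjects by default (the sample
  size at the level the random effects enter); a flag switches to the number
  of observations
- k counts fixed effects + estimated random-effect variances + residual-error
  parameters
- weights w_j = exp(-Delta_j/2) / sum_m exp(-Delta_m/2) with
  Delta_j = IC_j - min IC, computed shift-stably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = ["aic", "aicc", "bic", "ic_weights", "ICRow", "ICTable",
           "compare_models", "format_weight"]


def aic(minus2ll: float, k: int) -> float:
    """Akaike information criterion -2LL + 2k."""
    if k < 1:
        raise DomainError("k must be >= 1")
    return float(minus2ll) + 2.0 * k


def aicc(aic_value: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise DomainError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return float(aic_value) + 2.0 * k * (k + 1) / (n - k - 1)


def bic(minus2ll: float, k: int, sample_size: int) -> float:
    """Bayesian information criterion -2LL + k ln(sample_size)."""
    if sample_size < 2:
        raise DomainError("sample_size must be >= 2")
    return float(minus2ll) + k * math.log(sample_size)


def ic_weights(values) -> np.ndarray:
    """Evidence weights exp(-Delta_j/2) normalized over the candidate set.

    Shift-stable (depends only on IC differences) and safe for spreads of
    thousands of IC units.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1 or not np.all(np.isfinite(v)):
        raise DomainError("ic_weights requires at least one finite value")
    d = v - v.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def format_weight(w: float) -> str:
    """Report-style rendering: 4 decimals, scientific below 1e-4."""
    if w < 1e-4:
        return f"{w:.2E}"
    return f"{w:.4f}"


@dataclass
class ICRow:
    model_id: str
    minus2LL: float
    k: int
    n: int  # observations (AICc)
    N: int  # subjects (BIC default)
    AIC: float = 0.0
    AICc: float = 0.0
    BIC: float = 0.0
    w_AIC: float = 0.0
    w_AICc: float = 0.0
    w_BIC: float = 0.0


@dataclass
class ICTable:
    """Per-model criteria and weights, column order matching the field's
    standard comparison tables: model, -2LL, AIC, w(AIC), AICc, w(AICc),
    BIC, w(BIC)."""

    rows: list[ICRow]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.model_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate model ids in IC table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.model_id, r.minus2LL, r.AIC, r.w_AIC, r.AICc, r.w_AICc,
              r.BIC, r.w_BIC, r.k, r.n, r.N) for r in self.rows],
            columns=["model", "minus2LL", "AIC", "w_AIC", "AICc", "w_AICc",
                     "BIC", "w_BIC", "k", "n_obs", "n_subjects"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def to_markdown(self) -> str:
        lines = ["| model | -2LL | AIC | w(AIC) | AICc | w(AICc) | BIC | w(BIC) |",
                 "|---|---|---|---|---|---|---|---|"]
        for r in self.rows:
            lines.append(
                f"| {r.model_id} | {r.minus2LL:.2f} | {r.AIC:.2f} | {format_weight(r.w_AIC)} "
                f"| {r.AICc:.2f} | {format_weight(r.w_AICc)} | {r.BIC:.2f} "
                f"| {format_weight(r.w_BIC)} |")
        return "\n".join(lines)

    def best(self, criterion: str = "AIC") -> str:
        """Model id with the minimal criterion; ties broken by input order."""
        vals = [getattr(r, criterion) for r in self.rows]
        return self.rows[int(np.argmin(vals))].model_id


def build_table(entries, bic_sample_size: str = "subjects") -> ICTable:
    """Assemble an ICTable from (model_id, minus2LL, k, n_obs, n_subjects) tuples."""
    rows = []
    for model_id, m2ll, k, n, N in entries:
        r = ICRow(model_id=model_id, minus2LL=float(m2ll), k=int(k), n=int(n), N=int(N))
        r.AIC = aic(r.minus2LL, r.k)
        r.AICc = aicc(r.AIC, r.k, r.n)
        r.BIC = bic(r.minus2LL, r.k, r.N if bic_sample_size == "subjects" else r.n)
        rows.append(r)
    for crit, attr in (("AIC", "w_AIC"), ("AICc", "w_AICc"), ("BIC", "w_BIC")):
        w = ic_weights([getattr(r, crit) for r in rows])
        for r, wi in zip(rows, w):
            setattr(r, attr, float(wi))
    return ICTable(rows=rows, meta={
        "bic_sample_size": bic_sample_size,
        "definitions": "AIC=-2LL+2k; AICc=AIC+2k(k+1)/(n-k-1), n=observations; "
                       f"BIC=-2LL+k*ln({bic_sample_size}); "
                       "k = fixed effects + RE variances + error parameters",
    })


def compare_models(fits, bic_sample_size: str = "subjects", k_override=None) -> ICTable:
    """IC comparison of fitted models sharing one cohort.

    ``fits`` is a list of :class:`~tumornlme.nlme.FitResult`; a mismatch in the
    underlying data fingerprints raises ConfigurationError.  ``k_override``
    optionally maps model_id -> k for sensitivity analyses of the parameter
    count.
    """
    if not fits:
        raise ConfigurationError("no fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ConfigurationError("fits were not computed on the same cohort")
    entries = []
    for f in fits:
        k = (k_override or {}).get(f.model_id, f.k)
        entries.append((f.model_id, f.minus2LL, k, f.n_obs, f.n_subjects))
    return build_table(entries, bic_sample_size=bic_sample_size)
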