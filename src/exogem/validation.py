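"""Leave-one-metabolite-out cross-validation of patient-specific models.

For each measured exchange reaction, the patient model is rebuilt with
that single exchange relaxed to its baseline envelope, the relaxed
model is resampled, and the constrained vs relaxed flux populations for
that exchange are compared with a Welch two-sample t-test.  Raw
p-values are Benjamini-Hochberg adjusted over the whole run.  Under the
default convention a prediction is "correct" when the adjusted p-value
is *not* below alpha (no detectable discrepancy between constrained
prediction and relaxed behavior); the opposite convention is available
via ``significant_is_correct=True``.

Both populations are subsampled before testing — with thousands of
sampler draws a t-test would reject on trivially small differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .integrate import BaselineProfile
from .model import InfeasibleModelError, MetabolicModel
from .sampling import FluxSampleSet, sample_fluxes

__all__ = ["ValidationReport", "fdr_adjust", "crossvalidate_exchanges", "count_validation_cells"]


@dataclass
class ValidationReport:
    table: pd.DataFrame  # columns: exchange_id, p_raw, p_adjusted, verdict
    alpha: float
    n_errors: int = 0

    @property
    def fraction_correct(self) -> float:
        evaluated = self.table[self.table["verdict"] != "error"]
        if len(evaluated) == 0:
            return float("nan")
        return float((evaluated["verdict"] == "correct").mean())

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def count_validation_cells(n_patients: int, n_metabolites: int) -> int:
    """Number of (patient, metabolite) cross-validation tests enumerated."""
    return len([(p, m) for p in range(n_patients) for m in range(n_metabolites)])


def crossvalidate_exchanges(
    patient_model: MetabolicModel,
    baseline_profile: BaselineProfile,
    samples_constrained: FluxSampleSet,
    measured_exchanges: list[str],
    alpha: float = 0.01,
    subsample_n: int = 100,
    seed: int = 0,
    n_sample_points: int = 1000,
    thinning: int = 5,
    significant_is_correct: bool = False,
) -> ValidationReport:
    """Leave-one-exchange-out validation of one patient model."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    raw_ps = []
    n_errors = 0
    for k, rid in enumerate(measured_exchanges):
        if rid not in patient_model._rxn_index:
            raise KeyError(f"measured exchange {rid!r} not in model")
        relaxed = patient_model.copy()
        lo, hi = baseline_profile.bounds(rid)
        relaxed.set_bounds(rid, lo, hi)
        try:
            unconstrained = sample_fluxes(
                relaxed, n_sample_points, seed=seed + 104729 * (k + 1), thinning=thinning
            )
        except InfeasibleModelError:
            rows.append((rid, np.nan, np.nan, "error"))
            n_errors += 1
            continue
        a = samples_constrained.column(rid)
        b = unconstrained.column(rid)
        a_sub = rng.choice(a, size=min(subsample_n, len(a)), replace=False)
        b_sub = rng.choice(b, size=min(subsample_n, len(b)), replace=False)
        if np.ptp(a_sub) == 0 and np.ptp(b_sub) == 0:
            p = 1.0 if abs(a_sub.mean() - b_sub.mean()) < 1e-12 else 0.0
        else:
            p = float(_stats.ttest_ind(a_sub, b_sub, equal_var=False).pvalue)
        raw_ps.append(p)
        rows.append((rid, p, np.nan, None))

    tested = [i for i, r in enumerate(rows) if r[3] is None]
    adjusted = fdr_adjust([rows[i][1] for i in tested]) if tested else np.array([])
    out_rows = []
    for i, (rid, p_raw, _, verdict) in enumerate(rows):
        if verdict == "error":
            out_rows.append((rid, p_raw, np.nan, "error"))
            continue
        p_adj = float(adjusted[tested.index(i)])
        significant = p_adj < alpha
        correct = significant if significant_is_correct else not significant
        out_rows.append((rid, p_raw, p_adj, "correct" if correct else "incorrect"))
    table = pd.DataFrame(
        out_rows, columns=["exchange_id", "p_raw", "p_adjusted", "verdict"]
    )
    return ValidationReport(table=table, alpha=alpha, n_errors=n_errors)
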