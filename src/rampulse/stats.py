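"""Paired cohort comparison of ramped versus rectangular pulse shapes.

Each ramped shape is compared against the rectangular reference on the four
growth-function parameters (MaxFR, threshold, charge at MaxFR, dynamic
range), restricted to recordings with significant responses under *both*
shapes.  Group values are reported as mean ± sem and compared with
two-tailed Wilcoxon signed-rank tests at alpha = 0.05; scatter summaries
count recordings above/below the identity diagonal.

The signed-rank test drops zero differences before ranking (Wilcoxon's
original treatment) and uses average ranks for tied absolute differences.
The null distribution is exact (computed by convolving the rank-sum
generating function) up to n = 25 pairs and a normal approximation with
tie correction beyond, so fixture-scale p-values are exactly reproducible
while cohort-scale tests use the standard large-sample form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .growth import PARAM_NAMES

__all__ = [
    "PairedCohort",
    "CohortError",
    "UndefinedTestError",
    "pair_recordings",
    "signed_rank_test",
    "diagonal_counts",
    "summarize",
]

#: Parameters compared between shapes; DynRange80 is computed and reported
#: although reference tables print only the first four.
COMPARED_PARAMS = PARAM_NAMES + ("dyn_range80_nC",)

PARAM_LABELS = {
    "max_fr_Hz": "Maximal Firing Rate",
    "threshold_nC": "Threshold",
    "charge_at_max_nC": "Charge level at MaxFR",
    "dyn_range_nC": "Dynamic range",
    "dyn_range80_nC": "DynRange80",
}


class CohortError(ValueError):
    """Paired cohort cannot be formed."""


class UndefinedTestError(ValueError):
    """Signed-rank test undefined (no non-zero differences)."""


@dataclass
class PairedCohort:
    """Doubly-significant paired parameter values for one shape comparison.

    ``table`` is long format with columns ``recording_id, parameter,
    ref_value, shape_value``; ``n`` is the number of included recordings.
    """

    table: pd.DataFrame
    ref_shape: str
    comp_shape: str
    n: int


def pair_recordings(
    results: pd.DataFrame,
    ref_shape: str,
    comp_shape: str,
    params: tuple[str, ...] = COMPARED_PARAMS,
) -> PairedCohort:
    """Pair per-recording parameters of one ramped shape with the reference.

    ``results`` is a quantification table (one row per recording x shape,
    as from :func:`rampulse.growth.quantify_events`).  Only recordings whose
    responses were significant under both shapes are included, matching how
    reference cohorts are counted.
    """
    ref = results[results["shape_id"] == ref_shape].set_index("recording_id")
    comp = results[results["shape_id"] == comp_shape].set_index("recording_id")
    common = ref.index.intersection(comp.index)
    if len(common) == 0:
        raise CohortError(
            f"no recordings shared between shapes {ref_shape!r} and {comp_shape!r}"
        )
    both_sig = common[
        ref.loc[common, "significant"].to_numpy()
        & comp.loc[common, "significant"].to_numpy()
    ]
    if len(both_sig) == 0:
        raise CohortError("no recording is significant under both shapes")
    rows = []
    for p in params:
        rows.append(
            pd.DataFrame(
                {
                    "recording_id": both_sig,
                    "parameter": p,
                    "ref_value": ref.loc[both_sig, p].to_numpy(),
                    "shape_value": comp.loc[both_sig, p].to_numpy(),
                }
            )
        )
    return PairedCohort(
        table=pd.concat(rows, ignore_index=True),
        ref_shape=ref_shape,
        comp_shape=comp_shape,
        n=len(both_sig),
    )


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-tailed exact p by enumerating the rank-sum null distribution.

    Average ranks can be half-integral, so ranks are doubled to land the
    generating-function convolution on an integer lattice.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    # pmf of W+ (doubled scale) under random signs: product of (1 + x^r) / 2
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2 * w_plus))
    lo = pmf[: w2 + 1].sum()
    hi = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def signed_rank_test(
    x: np.ndarray,
    y: np.ndarray | None = None,
    *,
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired values.

    Pass paired samples ``(x, y)`` (differences ``x - y``) or a single array
    of differences.  Zero differences are dropped; tied absolute differences
    receive average ranks.  Returns ``(W+, p)`` where ``W+`` is the sum of
    ranks of positive differences.  The null distribution is exact for
    ``n <= exact_max_n`` pairs and a tie-corrected normal approximation
    (no continuity correction) otherwise.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, p


def diagonal_counts(
    ref: np.ndarray, shape: np.ndarray
) -> tuple[int, int, int]:
    """Scattergram counts: (above, below, on) the identity diagonal.

    With the reference on the x-axis and the ramped shape on the y-axis,
    "above" means the shape value exceeds the reference value.
    """
    ref = np.asarray(ref, dtype=float)
    shape = np.asarray(shape, dtype=float)
    ok = np.isfinite(ref) & np.isfinite(shape)
    ref, shape = ref[ok], shape[ok]
    above = int((shape > ref).sum())
    below = int((shape < ref).sum())
    ties = int((shape == ref).sum())
    return above, below, ties


def summarize(cohort: PairedCohort, *, min_n_test: int = 5) -> pd.DataFrame:
    """Per-parameter comparison summary for one shape pair.

    One row per parameter with mean ± sem under each shape, the two-tailed
    signed-rank p-value (NaN, flagged in ``test_note``, when fewer than
    ``min_n_test`` informative pairs exist), the pair count and the
    diagonal scatter counts.
    """
    out = []
    for p, sub in cohort.table.groupby("parameter", sort=False):
        ref_v = sub["ref_value"].to_numpy()
        shp_v = sub["shape_value"].to_numpy()
        ok = np.isfinite(ref_v) & np.isfinite(shp_v)
        ref_v, shp_v = ref_v[ok], shp_v[ok]
        n = len(ref_v)
        above, below, ties = diagonal_counts(ref_v, shp_v)
        note = ""
        pval = np.nan
        stat = np.nan
        nz = int((shp_v != ref_v).sum())
        if n < min_n_test or nz < min_n_test:
            note = f"test skipped (fewer than {min_n_test} informative pairs)"
        else:
            try:
                stat, pval = signed_rank_test(shp_v, ref_v)
            except UndefinedTestError:
                note = "test undefined (all differences zero)"
        out.append(
            {
                "parameter": p,
                "label": PARAM_LABELS.get(p, p),
                "ref_shape": cohort.ref_shape,
                "comp_shape": cohort.comp_shape,
                "n": n,
                "ref_mean": ref_v.mean() if n else np.nan,
                "ref_sem": sps.sem(ref_v) if n > 1 else 0.0 if n else np.nan,
                "comp_mean": shp_v.mean() if n else np.nan,
                "comp_sem": sps.sem(shp_v) if n > 1 else 0.0 if n else np.nan,
                "statistic": stat,
                "p_value": pval,
                "above_diagonal": above,
                "below_diagonal": below,
                "on_diagonal": ties,
                "in_reference_tables": p in PARAM_NAMES,
                "test_note": note,
            }
        )
    return pd.DataFrame(out)
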