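"""Exon-usage and splicing-coordination statistics.

Given isoform counts, computes the marginal use of each variant per cluster,
the expected frequency of every exon combination under independent choice
(the product of marginal frequencies), and an observed-vs-expected test per
combination: an exact two-sided binomial test with Benjamini–Hochberg FDR
control, flagging combinations at q <= alpha.  Replicate agreement is
summarized as a Pearson correlation of log abundances with a Fisher
z-transformation p-value.

Note: the expected-combination null here is deterministic (products of the
observed marginals), so a calibrated exact binomial test is used rather than
a two-condition count model; output frames carry this note in their ``attrs``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decode import CountTable
from .errors import ModelError
from .model import GeneModel

_METHOD_NOTE = (
    "expected = product of marginal exon frequencies (independence null); "
    "p = exact two-sided binomial; q = Benjamini-Hochberg"
)


def marginal_exon_freq(
    count_table: CountTable | dict[str, int], model: GeneModel
) -> dict[str, dict[str, float]]:
    """Per-cluster variant-use fractions from assigned isoform counts.

    Returns ``{region_id: {variant_id: fraction}}``; fractions within each
    cluster sum to 1.
    """
    counts = count_table.counts if isinstance(count_table, CountTable) else dict(count_table)
    if not counts or sum(counts.values()) == 0:
        raise ModelError("empty count table")
    vregions = model.variant_regions
    totals: dict[str, dict[str, float]] = {r.id: {} for r in vregions}
    grand = 0
    for key, n in counts.items():
        parts = key.split("|") if key else []
        if len(parts) != len(vregions):
            raise ModelError(f"isoform key {key!r} does not match model clusters")
        grand += n
        for region, vid in zip(vregions, parts):
            totals[region.id][vid] = totals[region.id].get(vid, 0) + n
    return {
        rid: {vid: c / grand for vid, c in sorted(per.items())}
        for rid, per in totals.items()
    }


def expected_combinations(
    marginals: dict[str, dict[str, float]],
    which: tuple[str, ...],
) -> dict[str, float]:
    """Expected frequency of every combination of the chosen clusters.

    ``expected(combo) = prod_i marginal[cluster_i][variant_i]``; the complete
    set over the clusters' variant products sums to 1.
    """
    missing = [c for c in which if c not in marginals]
    if missing:
        raise ModelError(f"clusters not in marginals: {missing}")
    pools = [sorted(marginals[c]) for c in which]
    out: dict[str, float] = {}
    for combo in itertools.product(*pools):
        f = 1.0
        for c, vid in zip(which, combo):
            f *= marginals[c][vid]
        out["|".join(combo)] = f
    return out


def combination_counts(
    count_table: CountTable | dict[str, int],
    model: GeneModel,
    which: tuple[str, ...],
) -> dict[str, int]:
    """Observed counts marginalized onto a subset of clusters."""
    counts = count_table.counts if isinstance(count_table, CountTable) else dict(count_table)
    vregions = [r.id for r in model.variant_regions]
    idx = [vregions.index(c) for c in which]
    out: dict[str, int] = {}
    for key, n in counts.items():
        parts = key.split("|")
        combo = "|".join(parts[i] for i in idx)
        out[combo] = out.get(combo, 0) + n
    return out


def coordination_test(
    observed_counts: dict[str, int],
    expected_freqs: dict[str, float],
    total: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Observed-vs-expected test per exon combination.

    Each combination's observed count is tested against its expected
    frequency with an exact two-sided binomial test at n = total; q-values
    are Benjamini–Hochberg, and combinations with q <= alpha are flagged.
    Combinations with expected count < 1 are tested but annotated
    ``low_power``.  Returns a DataFrame sorted by q.
    """
    unknown = set(observed_counts) - set(expected_freqs)
    if unknown:
        raise ModelError(f"observed combinations missing from expected: {sorted(unknown)[:5]}")
    if total is None:
        total = sum(observed_counts.values())
    if total == 0:
        raise ModelError("total observed count is zero")
    rows = []
    for combo in sorted(expected_freqs):
        k = int(observed_counts.get(combo, 0))
        p_exp = float(expected_freqs[combo])
        if 0.0 < p_exp < 1.0:
            pval = sps.binomtest(k, total, p_exp, alternative="two-sided").pvalue
        elif p_exp == 0.0:
            pval = 1.0 if k == 0 else 0.0
        else:  # p_exp == 1.0
            pval = 1.0 if k == total else 0.0
        rows.append(
            {
                "combination": combo,
                "observed": k,
                "expected_freq": p_exp,
                "expected_count": p_exp * total,
                "p": float(pval),
            }
        )
    df = pd.DataFrame(rows)
    _rej, q, _a, _b = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    df["q"] = q
    df["flagged"] = df["q"] <= alpha
    df["low_power"] = df["expected_count"] < 1
    df.attrs["method"] = _METHOD_NOTE
    return df.sort_values("q", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class CorrelationResult:
    """Replicate agreement: Pearson r on log abundances, Fisher-z p-value."""

    r: float
    p: float
    n: int


def replicate_correlation(
    table_a: CountTable | dict[str, int],
    table_b: CountTable | dict[str, int],
    pseudo_count: float = 1.0,
) -> CorrelationResult:
    """Pearson correlation of log(count + pseudo_count) over the key union.

    Significance comes from the Fisher z-transformation:
    ``z = atanh(r) * sqrt(n - 3)`` against a standard normal (two-sided).
    Requires at least 4 shared keys.
    """
    a = table_a.counts if isinstance(table_a, CountTable) else dict(table_a)
    b = table_b.counts if isinstance(table_b, CountTable) else dict(table_b)
    keys = sorted(set(a) | set(b))
    n = len(keys)
    if n < 4:
        raise ModelError(f"need >= 4 keys for Fisher-z correlation, got {n}")
    xa = np.log([a.get(k, 0) + pseudo_count for k in keys])
    xb = np.log([b.get(k, 0) + pseudo_count for k in keys])
    if xa.std() == 0 or xb.std() == 0:
        raise ModelError("degenerate (constant) abundance vector")
    r = float(np.corrcoef(xa, xb)[0, 1])
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    z = math.atanh(r_c) * math.sqrt(n - 3)
    p = float(min(max(2.0 * sps.norm.sf(abs(z)), np.nextafter(0, 1)), 1.0))
    return CorrelationResult(r=r, p=p, n=n)
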