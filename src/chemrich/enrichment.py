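"""Self-contained set enrichment statistics.

Each metabolite set is tested with a two-sided one-sample
Kolmogorov-Smirnov test of its members' raw p-values against the
Uniform(0,1) null (the distribution p-values follow when nothing is
going on).  Because the reference distribution is theoretical, the set
p-value does not depend on any background compound database.  Set-level
p-values are then adjusted across all tested sets with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ontology import ChemSet

__all__ = [
    "KSResult",
    "EnrichmentRow",
    "ks_uniform_test",
    "bh_fdr",
    "set_statistics",
    "EXACT_N_LIMIT",
]

EXACT_N_LIMIT = 100  # exact small-sample distribution below this n


@dataclass(frozen=True)
class KSResult:
    """One-sample KS test outcome against Uniform(0,1)."""

    n: int
    D: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def ks_statistic(pvals: np.ndarray) -> float:
    """Two-sided sup-norm distance between the empirical CDF and Uniform(0,1).

    ``D = max_i max(i/n - x_(i), x_(i) - (i-1)/n)`` over the sorted sample.
    """
    x = np.sort(pvals)
    n = x.size
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - x, x - (i - 1) / n)))


def ks_uniform_test(pvals) -> KSResult:
    """Two-sided one-sample KS test of p-values against Uniform(0,1).

    The exact small-sample distribution is used for n < 100; ties in the
    sample keep the exact method (with a warning) because rounded member
    p-values are common and the asymptotic approximation is drastically
    wrong for small sets.  For n >= 100 the asymptotic Kolmogorov
    distribution is used.
    """
    x = np.asarray(list(pvals), dtype=float)
    if x.size == 0:
        raise ValueError("empty p-value sample")
    if np.any((x < 0) | (x > 1)) or np.any(np.isnan(x)):
        raise ValueError("p-values must lie in [0, 1]")
    n = x.size
    d = ks_statistic(x)
    if n < EXACT_N_LIMIT:
        if np.unique(x).size < n:
            warnings.warn(
                "ties among member p-values; exact KS method retained",
                stacklevel=2,
            )
        p = float(stats.kstwo.sf(d, n))
        method = "exact"
    else:
        p = float(stats.kstwobign.sf(d * math.sqrt(n)))
        method = "asymptotic"
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return KSResult(n=n, D=d, p_value=p, method=method)


def bh_fdr(set_pvals: dict[str, float], m: int | None = None) -> dict[str, float]:
    """Benjamini-Hochberg step-up adjustment of set-level p-values.

    ``m`` is the number of hypotheses tested (default: the number of
    p-values provided); it may exceed the number of provided values when
    additional sets were tested but are not being adjusted here.
    Adjusted_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.
    """
    labels = list(set_pvals)
    p = np.asarray([set_pvals[l] for l in labels], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"m={m} smaller than number of p-values ({k})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(k)
    out[order] = adjusted
    return dict(zip(labels, out.tolist()))


@dataclass
class EnrichmentRow:
    """Per-set enrichment result (one output table row)."""

    set_label: str
    size: int
    ks_p: float
    fdr: float
    n_altered: int
    n_increased: int
    n_decreased: int
    n_flat_fold_change: int  # altered members with fold change exactly 1
    tree_position: int = 0
    provenance: str = "mesh_direct"
    ks_method: str = "exact"


def set_statistics(
    chemset: ChemSet,
    records,
    alpha: float = 0.05,
) -> EnrichmentRow:
    """KS p-value and direction counts for one metabolite set.

    A member is "altered" when its raw per-metabolite p-value is below
    ``alpha``; altered members split into increased (fold change > 1) and
    decreased (fold change < 1), with fold change exactly 1 counted in
    neither direction.  The ``fdr`` field is filled in later by
    :func:`bh_fdr` across all tested sets.
    """
    by_id = {r.compound_id: r for r in getattr(records, "records", records)}
    members = []
    for cid in chemset.compound_ids:
        if cid not in by_id:
            raise ValueError(
                f"set {chemset.label!r}: member {cid!r} missing from records"
            )
        members.append(by_id[cid])
    ks = ks_uniform_test([m.effect_p for m in members])
    altered = [m for m in members if m.effect_p < alpha]
    inc = sum(1 for m in altered if m.fold_change > 1)
    dec = sum(1 for m in altered if m.fold_change < 1)
    return EnrichmentRow(
        set_label=chemset.label,
        size=len(members),
        ks_p=ks.p_value,
        fdr=math.nan,
        n_altered=len(altered),
        n_increased=inc,
        n_decreased=dec,
        n_flat_fold_change=len(altered) - inc - dec,
        provenance=chemset.provenance,
        ks_method=ks.method,
    )
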