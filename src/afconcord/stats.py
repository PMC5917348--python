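"""Region-wise concordance and outcome statistics.

Two "raters" — clinical ECGI phase mapping and substrate simulation —
each label the 7 atrial regions of a patient as RD-harboring or not.
This module classifies regions (ECGI+/Sim+ etc.), pools per-patient
classifications into a 2x2 table, and computes the agreement and outcome
statistics used in the analysis: percent agreement, Cohen's kappa, the
intraclass (Kraemer-style) kappa_0 variant, Fisher's exact test, the exact
Wilcoxon signed-rank test, and median [IQR] summaries with the positional
(n+1)p quantile convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

ALL_REGIONS = tuple(range(1, 8))

#: The four region classification labels.
LABELS = ("ECGI+/Sim+", "ECGI+/Sim-", "ECGI-/Sim+", "ECGI-/Sim-")


# ---------------------------------------------------------------------------
# Region assignment and classification
# ---------------------------------------------------------------------------

def assign_rd_region(rd, grid) -> int:
    """Region harboring a reentrant driver.

    The driver is assigned to the region in which the plurality of its
    phase-singularity points lie.  Ties are broken by the region of the
    chronologically latest PS point, then by the lowest region id, so the
    assignment is deterministic.

    Parameters
    ----------
    rd : ReentrantDriver or PSTrajectory
        Object exposing a ``points`` sequence of PS points with ``x``/``y``
        in mm (or itself such a trajectory via ``rd.trajectory``).
    grid : TissueGrid
        Provides ``region_id`` per node and spacing ``dx``.
    """
    traj = getattr(rd, "trajectory", rd)
    points = traj.points
    if len(points) == 0:
        raise ValueError("empty trajectory has no region")
    regions = [_region_at(grid, p.x, p.y) for p in points]
    counts: dict[int, int] = {}
    for r in regions:
        counts[r] = counts.get(r, 0) + 1
    best = max(counts.values())
    tied = sorted(r for r, c in counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    last_region = regions[-1]
    if last_region in tied:
        return last_region
    return tied[0]


def _region_at(grid, x_mm: float, y_mm: float) -> int:
    ix = int(round(x_mm / grid.dx))
    iy = int(round(y_mm / grid.dx))
    ix = min(max(ix, 0), grid.nx - 1)
    iy = min(max(iy, 0), grid.ny - 1)
    return int(grid.region_id[iy, ix])


@dataclass(frozen=True)
class RegionClassification:
    """Per-patient ECGI/Sim labels over the 7 anatomical regions."""

    patient_id: object
    labels: Mapping[int, str]

    def __post_init__(self):
        if sorted(self.labels) != list(ALL_REGIONS):
            raise ValueError("classification must label exactly regions 1..7")
        bad = set(self.labels.values()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {bad}")


def classify_patient(sim_regions: Iterable[int], ecgi_regions: Iterable[int],
                     patient_id: object = None) -> RegionClassification:
    """Label each of the 7 regions by membership in the two RD-region sets."""
    sim = set(sim_regions)
    ecgi = set(ecgi_regions)
    for s in (sim, ecgi):
        if not s <= set(ALL_REGIONS):
            raise ValueError(f"region ids outside 1..7: {s - set(ALL_REGIONS)}")
    labels = {}
    for r in ALL_REGIONS:
        e, s = r in ecgi, r in sim
        labels[r] = ("ECGI+/Sim+" if e and s else
                     "ECGI+/Sim-" if e else
                     "ECGI-/Sim+" if s else "ECGI-/Sim-")
    return RegionClassification(patient_id=patient_id, labels=labels)


@dataclass(frozen=True)
class ConcordanceTable:
    """Pooled 2x2 counts: a=#(++), b=#(+-), c=#(-+), d=#(--)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def percent_agreement(self) -> float:
        if self.n == 0:
            raise ValueError("empty table")
        return (self.a + self.d) / self.n


def pool_concordance(classifications: Iterable[RegionClassification]) -> ConcordanceTable:
    """Sum per-patient region labels into the pooled 2x2 table."""
    counts = dict.fromkeys(LABELS, 0)
    for cl in classifications:
        for lab in cl.labels.values():
            counts[lab] += 1
    return ConcordanceTable(a=counts["ECGI+/Sim+"], b=counts["ECGI+/Sim-"],
                            c=counts["ECGI-/Sim+"], d=counts["ECGI-/Sim-"])


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def cohen_kappa(table: ConcordanceTable) -> tuple[float, bool]:
    """Cohen's kappa for the pooled 2x2 table.

    Chance agreement uses the product of the two raters' marginals.
    Returns ``(kappa, degenerate)``; when any marginal is zero (one rater
    never/always positive) kappa is undefined and ``(0.0, True)`` is
    returned, matching the convention that a rater with no variability
    carries no chance-corrected information.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    p_ecgi = (a + b) / n
    p_sim = (a + c) / n
    margins = (p_ecgi, 1 - p_ecgi, p_sim, 1 - p_sim)
    if any(m == 0 for m in margins):
        return 0.0, True
    p_o = (a + d) / n
    p_e = p_ecgi * p_sim + (1 - p_ecgi) * (1 - p_sim)
    return (p_o - p_e) / (1 - p_e), False


def kraemer_kappa0(table: ConcordanceTable) -> tuple[float, bool]:
    """Intraclass-style kappa_0 (raters treated as interchangeable).

    Chance agreement is computed from the mean positive rate of the two
    raters, p_bar: p_e = p_bar^2 + (1 - p_bar)^2.  Degenerate when p_bar is
    0 or 1 (no variability at all), in which case ``(0.0, True)``.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    p_bar = ((a + b) / n + (a + c) / n) / 2
    if p_bar in (0.0, 1.0):
        return 0.0, True
    p_o = (a + d) / n
    p_e = p_bar ** 2 + (1 - p_bar) ** 2
    return (p_o - p_e) / (1 - p_e), False


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for proportions k1/n1 vs k2/n2.

    Sums hypergeometric probabilities of all tables (at fixed margins) no
    more probable than the observed one.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         max_exact_n: int = 25) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; tied absolute differences receive
    midranks.  For effective n <= ``max_exact_n`` the exact null
    distribution of the positive-rank sum is built by dynamic programming
    over all 2^n sign assignments (midranks doubled to keep integer sums);
    beyond that a normal approximation with tie correction is used.
    All-zero differences give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= max_exact_n:
        # doubled midranks are integers; DP over achievable doubled sums
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r]
        counts /= counts.sum()
        w2 = int(round(2 * w_pos))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        return float(min(1.0, 2 * min(p_le, p_ge)))
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", mode="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _round_half_away(v: float, decimals: int = 1) -> float:
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(v) * scale + 0.5 + 1e-12), v) / scale


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with the positional h = (n+1)p quantile convention.

    Quantiles are taken at h = (n+1)p with linear interpolation between
    order statistics (numpy's ``weibull`` method) and rounded to one
    decimal, half away from zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="weibull")
    return (_round_half_away(med), _round_half_away(q1), _round_half_away(q3))


def percent(k: int, n: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if n <= 0:
        raise ValueError("n must be positive")
    return int(_round_half_away(100.0 * k / n, decimals=0))


@dataclass
class OutcomeSummary:
    """Per-class acute ablation response summary."""

    region_class: str
    n: int
    termination_rate_pct: int | None
    positive_rate_pct: int | None
    delta_cl_median_iqr: tuple[float, float, float] | None
    defined: bool = True


def outcome_tabulation(targets: Iterable[Mapping]) -> dict[str, OutcomeSummary]:
    """Summarize acute response per region class over ablation targets.

    Each target record carries ``region_class``, ``terminated`` (bool),
    ``positive_response`` (bool) and, for non-terminating targets,
    ``delta_cl`` (ms).  Classes with no targets are flagged undefined.
    """
    by_class: dict[str, list[Mapping]] = {lab: [] for lab in LABELS}
    for t in targets:
        by_class.setdefault(t["region_class"], []).append(t)
    out: dict[str, OutcomeSummary] = {}
    for lab, recs in by_class.items():
        if not recs:
            out[lab] = OutcomeSummary(lab, 0, None, None, None, defined=False)
            continue
        n = len(recs)
        n_term = sum(bool(r["terminated"]) for r in recs)
        n_pos = sum(bool(r["positive_response"]) for r in recs)
        dcl = [r["delta_cl"] for r in recs
               if not r["terminated"] and r.get("delta_cl") is not None]
        out[lab] = OutcomeSummary(
            region_class=lab,
            n=n,
            termination_rate_pct=percent(n_term, n),
            positive_rate_pct=percent(n_pos, n),
            delta_cl_median_iqr=median_iqr(dcl) if dcl else None,
        )
    return out
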