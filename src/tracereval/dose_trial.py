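"""Dose-group statistics and the dose-escalation decision engine.

The trial design is a 4 x 3 step-up: three patients at each of four
ascending doses, after which the best-performing dose group (by median
TBR) and one de-escalating dose are expanded to ten patients each.
Group comparisons are nonparametric throughout (none of the trial's
endpoints were normally distributed): Kruskal-Wallis with Dunn's
post-hoc across dose groups, Mann-Whitney U within groups, Spearman for
clinicopathological correlations, all two-sided at the 0.05 level.
A plateau of the TBR across consecutive doses marks the optimal dose.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quantify import QuantRecord
from .synthetic import PatientRecord

ALPHA = 0.05


@dataclass
class DoseGroupSummary:
    dose_mg: float
    n: int
    tumor_mfi: list[float] = field(default_factory=list)
    background_mfi: list[float] = field(default_factory=list)
    tbr: list[float] = field(default_factory=list)
    medians: dict = field(default_factory=dict)
    boxplot: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _check_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs at least one observation")
    return arrs


def kruskal_wallis_dunn(groups: list, adjust: str = "bonferroni"):
    """Kruskal-Wallis H across groups with Dunn's pairwise post hoc.

    Returns (H, p, pairwise) where pairwise maps (i, j) group-index pairs
    to {'z', 'p_adjusted'}.  H and its asymptotic chi-square p are
    tie-corrected; Dunn's z uses the pooled mean-rank difference with the
    tie-corrected variance, adjusted over all pairs (Bonferroni default).
    """
    arrs = _check_groups(groups)
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    total_n = sum(a.size for a in arrs)
    if total_n < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:  # scipy refuses all-identical data; H is 0 by definition
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = stats.kruskal(*arrs)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    pos = 0
    for a in arrs:
        mean_ranks.append(ranks[pos:pos + a.size].mean())
        pos += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    n = total_n
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    pairs = list(itertools.combinations(range(len(arrs)), 2))
    pairwise = {}
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * len(pairs))
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        pairwise[(i, j)] = {"z": float(z), "p_adjusted": float(p_adj)}
    return float(h_stat), float(p), pairwise


def _mwu_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = x.size, y.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    lo_count = hi_count = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if u <= u_obs + 1e-12:
            lo_count += 1
        if u >= u_obs - 1e-12:
            hi_count += 1
    p = min(1.0, 2.0 * min(lo_count, hi_count) / total)
    return float(u_obs), p


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact p by full enumeration of relabelings when both samples have
    n <= 8 (ties handled through midranks); otherwise the tie-corrected
    normal approximation.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size <= 8 and y.size <= 8:
        return _mwu_exact_p(x, y)
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def select_expansion_groups(median_tbr_by_dose: dict[float, float]):
    """Pick the expansion doses after part I of the step-up design.

    Best = argmax of the median TBR (ties resolved toward the lower
    dose); its companion is the next dose below (next above, flagged,
    when the best sits at the lowest dose).  Returns
    (best_dose, companion_dose, flags).
    """
    doses = sorted(median_tbr_by_dose)
    if len(doses) < 2:
        raise ValueError("need at least two evaluable doses")
    best = max(doses, key=lambda d: (median_tbr_by_dose[d], -d))
    flags: list[str] = []
    idx = doses.index(best)
    if idx == 0:
        companion = doses[1]
        flags.append("best_at_lowest_dose")
    else:
        companion = doses[idx - 1]
    return best, companion, flags


def plateau_optimal_dose(median_tbr_by_dose: dict[float, float],
                         rel_threshold: float = 0.10):
    """First dose whose step to the next gains less than rel_threshold.

    Scans ascending consecutive dose pairs; the first dose d_i with
    (TBR_{i+1} - TBR_i)/TBR_i < rel_threshold is the optimal dose with
    plateau_found True.  Without any such step the highest dose is
    returned with plateau_found False.
    """
    doses = sorted(median_tbr_by_dose)
    if len(doses) < 2:
        raise ValueError("need at least two doses")
    tbrs = [median_tbr_by_dose[d] for d in doses]
    if any(t <= 0 for t in tbrs):
        raise ValueError("TBR values must be positive")
    for i in range(len(doses) - 1):
        if (tbrs[i + 1] - tbrs[i]) / tbrs[i] < rel_threshold:
            return doses[i], True
    return doses[-1], False


def _five_number(values: list[float]) -> dict:
    v = np.asarray(values, dtype=float)
    return {"median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
            "min": float(v.min()), "max": float(v.max())}


def group_summaries(records: list[QuantRecord],
                    cohort: list[PatientRecord]) -> dict:
    """Per-dose-group summaries plus the cross-group nonparametric tests.

    Boxplot statistics (median, quartiles, min-max whiskers) per group
    for tumor MFI, background MFI and TBR; Kruskal-Wallis across groups
    on each quantity, and within-group tumor-vs-background Mann-Whitney.
    Groups of one patient are flagged underpowered.
    """
    if not cohort or not records:
        raise ValueError("empty cohort or quantification set")
    dose_of = {p.patient_id: p.dose_mg for p in cohort}
    by_dose: dict[float, DoseGroupSummary] = {}
    for rec in records:
        dose = dose_of.get(rec.patient_id)
        if dose is None:
            continue
        g = by_dose.setdefault(dose, DoseGroupSummary(dose_mg=dose, n=0))
        g.n += 1
        if 1 in rec.mfi_by_class:
            g.tumor_mfi.append(rec.mfi_by_class[1])
        if "background" in rec.mfi_by_class:
            g.background_mfi.append(rec.mfi_by_class["background"])
        if rec.tbr is not None:
            g.tbr.append(rec.tbr)
    tests: dict = {}
    for g in by_dose.values():
        for name, vals in (("tumor_mfi", g.tumor_mfi),
                           ("background_mfi", g.background_mfi), ("tbr", g.tbr)):
            if vals:
                g.medians[name] = float(np.median(vals))
                g.boxplot[name] = _five_number(vals)
        if g.n < 2:
            g.flags.append("underpowered")
        if g.tumor_mfi and g.background_mfi and g.n >= 2:
            u, p = mann_whitney(g.tumor_mfi, g.background_mfi)
            tests[f"mwu_tumor_vs_background_{g.dose_mg:g}mg"] = {"U": u, "p": p}
    doses = sorted(by_dose)
    for name in ("tumor_mfi", "background_mfi", "tbr"):
        groups = [getattr(by_dose[d], name) for d in doses]
        groups = [g for g in groups if g]
        if len(groups) >= 2 and sum(len(g) for g in groups) >= 3:
            h, p, pairwise = kruskal_wallis_dunn(groups)
            tests[f"kw_{name}"] = {
                "H": h, "p": p,
                "dunn": {f"{doses[i]:g}v{doses[j]:g}": v
                         for (i, j), v in pairwise.items()},
            }
    return {"groups": [by_dose[d] for d in doses], "tests": tests}
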