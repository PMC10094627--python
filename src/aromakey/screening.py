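"""Odor-activity-value screening and per-compound group-difference tests.

A compound's odor activity value (OAV) in a district is its group-mean
relative concentration divided by its odor threshold in air; OAV > 1 marks
the compound as perceptible (aroma-active) there.  Key active differential
odorants are compounds that are both model-selected (VIP > 1) and
aroma-active in at least one district (max OAV > 1).  Group differences are
assessed with one-way ANOVA on injection-level concentrations, and the
"significantly higher than every other district" claim with one-vs-each
Welch t tests under Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CompoundCatalog, RunConfig, ValidationError

__all__ = [
    "OavMatrix",
    "ScreeningReport",
    "compute_oav",
    "screen_key_active",
    "anova_by_group",
    "top_group_flags",
    "build_screening_report",
]


@dataclass
class OavMatrix:
    """Compounds x districts OAV table.

    Only compounds with a known odor threshold appear; the rest are listed
    in ``excluded`` rather than imputed.
    """

    table: pd.DataFrame
    excluded: Tuple[str, ...] = ()

    @property
    def compounds(self) -> Tuple[str, ...]:
        return tuple(self.table.index)


@dataclass
class ScreeningReport:
    """Outcome of the VIP x OAV screen plus univariate statistics.

    ``key_active`` is always a subset of ``vip_selected``;
    ``qualifying_groups`` maps each screened compound to the districts where
    its OAV exceeds the cutoff.  ``anova`` maps compound to (F, p);
    ``top_groups`` maps compound to (district with the highest mean, flag),
    flag in {"none", "*", "**"}.
    """

    vip_selected: FrozenSet[str]
    key_active: FrozenSet[str]
    qualifying_groups: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    oav: Optional[OavMatrix] = None
    anova: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    top_groups: Dict[str, Tuple[Optional[str], str]] = field(default_factory=dict)


def compute_oav(group_means: pd.DataFrame, catalog: CompoundCatalog) -> OavMatrix:
    """OAV[c, g] = group-mean concentration / odor threshold in air.

    ``group_means`` is districts x compounds (as produced by
    :func:`aromakey.quantify.group_mean_concentrations`); the result is
    transposed to compounds x districts.  Compounds without a threshold are
    excluded and listed; a non-positive threshold is an error.
    """
    rows = {}
    excluded = []
    for cid in group_means.columns:
        rec = catalog[cid]
        ot = rec.odor_threshold_air
        if ot is None:
            excluded.append(cid)
            continue
        if not ot > 0:
            raise ValidationError(
                f"compound {cid!r}: odor threshold must be positive, got {ot}"
            )
        rows[cid] = group_means[cid] / ot
    table = pd.DataFrame(rows).T
    table.columns = group_means.index
    return OavMatrix(table=table, excluded=tuple(excluded))


def screen_key_active(
    vip: pd.Series, oav: OavMatrix, config: RunConfig
) -> ScreeningReport:
    """Apply the two-stage screen: VIP > cutoff, then max-district OAV > cutoff.

    Both cutoffs are strict inequalities.  ``qualifying_groups`` records,
    for every compound in the OAV table, the districts where it is
    aroma-active regardless of its VIP status.
    """
    vip_selected = frozenset(vip.index[vip > config.vip_cutoff])
    qualifying = {
        cid: frozenset(
            oav.table.columns[oav.table.loc[cid] > config.oav_cutoff]
        )
        for cid in oav.table.index
    }
    key_active = frozenset(
        cid
        for cid in oav.table.index
        if cid in vip_selected and len(qualifying[cid]) > 0
    )
    return ScreeningReport(
        vip_selected=vip_selected,
        key_active=key_active,
        qualifying_groups=qualifying,
        oav=oav,
    )


def _groups_of(conc: pd.DataFrame, compound: str):
    values = conc[compound]
    groups = conc.index.get_level_values("group")
    order = list(dict.fromkeys(groups))
    return [values[groups == g].to_numpy(dtype=float) for g in order], order


def anova_by_group(conc: pd.DataFrame, compound: str) -> Tuple[float, float]:
    """Classical one-way fixed-effects ANOVA on injection-level values.

    Returns (F, p).  Identical values in every injection give (0.0, 1.0)
    rather than an error.
    """
    samples, order = _groups_of(conc, compound)
    if len(order) < 2 or any(len(s) < 2 for s in samples):
        raise ValidationError(
            "ANOVA needs at least 2 groups with at least 2 injections each"
        )
    pooled = np.concatenate(samples)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    result = stats.f_oneway(*samples)
    return float(result.statistic), float(result.pvalue)


def top_group_flags(
    conc: pd.DataFrame, compound: str, config: RunConfig
) -> Tuple[Optional[str], str]:
    """Identify the district with the highest mean and its significance flag.

    The flag is ``"**"`` when the top district beats EVERY other district in
    one-sided Welch t tests with all Holm-adjusted p-values below
    ``strong_alpha``; ``"*"`` likewise at ``alpha``; ``"none"`` otherwise.
    An exact tie in group means yields ``(None, "none")``.
    """
    samples, order = _groups_of(conc, compound)
    means = np.array([s.mean() for s in samples])
    top_idx = int(np.argmax(means))
    if (means == means[top_idx]).sum() > 1:
        return None, "none"
    top = samples[top_idx]
    pvals = []
    for j, other in enumerate(samples):
        if j == top_idx:
            continue
        if np.allclose(top, top[0]) and np.allclose(other, other[0]):
            pvals.append(0.0 if top[0] > other[0] else 1.0)
            continue
        res = stats.ttest_ind(top, other, equal_var=False, alternative="greater")
        pvals.append(float(res.pvalue))
    adjusted = multipletests(pvals, method="holm")[1]
    if (adjusted < config.strong_alpha).all():
        flag = "**"
    elif (adjusted < config.alpha).all():
        flag = "*"
    else:
        flag = "none"
    return order[top_idx], flag


def build_screening_report(
    conc: pd.DataFrame,
    group_means: pd.DataFrame,
    catalog: CompoundCatalog,
    vip: pd.Series,
    config: RunConfig,
) -> ScreeningReport:
    """Full screening stage: OAV, VIP x OAV screen, ANOVA and top-group flags.

    Univariate statistics are computed for the key-active compounds (the set
    the screen reports); the OAV table covers every compound with a known
    threshold.
    """
    oav = compute_oav(group_means, catalog)
    report = screen_key_active(vip, oav, config)
    for cid in sorted(report.key_active):
        report.anova[cid] = anova_by_group(conc, cid)
        report.top_groups[cid] = top_group_flags(conc, cid, config)
    return report
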