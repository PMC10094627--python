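"""Internal-standard semi-quantification and chemical-class profiling.

Relative concentration is computed against the spiked ethyl decanoate::

    conc[i, c] (ng/g) = area[i, c] * is_mass_ng / (is_area[i] * dry_mass_g[i])

i.e. linear in the analyte peak area and inverse-linear in both the
internal-standard area and the sample dry mass.  This is semi-quantification:
it assumes a common response factor, so values are comparable across runs
but are not absolute amounts.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .datamodel import CompoundCatalog, PeakTable, ValidationError, CHEM_CLASSES

__all__ = ["semi_quantify", "group_mean_concentrations", "class_proportions"]

#: Names of the row MultiIndex levels of a concentration matrix.
INDEX_LEVELS = ("sample_id", "group", "replicate")


def semi_quantify(peaks: PeakTable) -> pd.DataFrame:
    """Convert raw peak areas to relative concentrations (ng/g dry mass).

    Returns a DataFrame with a (sample_id, group, replicate) MultiIndex and
    one column per compound.  Raises :class:`ValidationError` if any
    injection has a non-positive internal-standard area or dry mass.
    """
    compounds = list(peaks.catalog.ids)
    rows = []
    index = []
    for inj in peaks.injections:
        if not inj.is_peak_area > 0:
            raise ValidationError(
                f"injection {inj.sample_id}/r{inj.replicate}: internal-standard "
                f"area must be positive"
            )
        if not inj.dry_mass_g > 0:
            raise ValidationError(
                f"injection {inj.sample_id}/r{inj.replicate}: dry mass must be "
                f"positive"
            )
        scale = peaks.is_mass_ng / (inj.is_peak_area * inj.dry_mass_g)
        rows.append([inj.peak_areas.get(c, 0.0) * scale for c in compounds])
        index.append((inj.sample_id, inj.group, inj.replicate))
    frame = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=INDEX_LEVELS),
        columns=compounds,
    )
    if (frame.values < 0).any():
        raise ValidationError("negative concentration produced from negative area")
    return frame


def group_mean_concentrations(conc: pd.DataFrame) -> pd.DataFrame:
    """Average concentrations over all injections in each district group.

    With balanced replicate counts this equals the mean of per-sample means;
    for unbalanced inputs every injection still counts once.  Group order is
    order of first appearance.  Empty input raises.
    """
    if len(conc) == 0:
        raise ValidationError("cannot average an empty concentration matrix")
    groups = conc.index.get_level_values("group")
    order = list(dict.fromkeys(groups))
    means = conc.groupby(level="group", sort=False).mean()
    return means.loc[order]


def class_proportions(
    conc_or_means: pd.DataFrame, catalog: CompoundCatalog
) -> pd.DataFrame:
    """Percent of total concentration per chemical class, by district group.

    Shares are computed on group-mean concentrations: for each group,
    ``100 * sum(mean conc of class members) / sum(mean conc of all
    compounds)``.  Rows sum to 100.

    Accepts either an injection-level concentration matrix (with the
    standard MultiIndex) or an already-aggregated groups x compounds matrix.
    """
    if isinstance(conc_or_means.index, pd.MultiIndex):
        means = group_mean_concentrations(conc_or_means)
    else:
        means = conc_or_means
    class_of = {rec.compound_id: rec.chem_class for rec in catalog}
    missing = [c for c in means.columns if c not in class_of]
    if missing:
        raise ValidationError(f"compounds without catalog entry: {missing[:5]}")
    totals = means.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("group with zero total concentration")
    shares = pd.DataFrame(0.0, index=means.index, columns=list(CHEM_CLASSES))
    for cls in CHEM_CLASSES:
        members = [c for c in means.columns if class_of[c] == cls]
        if members:
            shares[cls] = 100.0 * means[members].sum(axis=1) / totals
    return shares
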