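"""Domain types shared by every stage of the volatile-flavor pipeline.

The pipeline works on identified GC-MS peak tables: each *injection* is one
chromatographic run of one tea sample, spiked with a fixed amount of ethyl
decanoate as internal standard.  Compounds live in a catalog that records
their chemical class (one of twelve), a free-text odor note, and - where the
literature provides one - an odor threshold in air on the same ng/g basis as
the semi-quantified concentrations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "CHEM_CLASSES",
    "DEFAULT_GROUPS",
    "DEFAULT_IS_MASS_NG",
    "ValidationError",
    "SchemaError",
    "normalize_name",
    "CompoundRecord",
    "CompoundCatalog",
    "InjectionRecord",
    "PeakTable",
    "RunConfig",
]

#: The twelve chemical classes used to bin volatile flavor compounds.
CHEM_CLASSES: Tuple[str, ...] = (
    "alcohol",
    "heterocyclic",
    "aldehyde",
    "ketone",
    "alkene",
    "acid",
    "aromatic_hydrocarbon",
    "ester",
    "alkane",
    "amino_acid",
    "phenol",
    "n_compound",
)

#: Default district groups for the Guangdong black-tea study design.  Yingde
#: is split into two variety groups (Yinghong No. 9 vs Hongyan No. 12).
DEFAULT_GROUPS: Tuple[str, ...] = (
    "YJ-Yingde",
    "HY-Yingde",
    "Luokeng",
    "Renhua",
    "Meizhou",
    "Heyuan",
    "Lianshan",
    "Chaozhou",
)

#: Internal-standard mass per injection: 20 uL of a 0.02 mg/mL ethyl
#: decanoate solution = 400 ng.
DEFAULT_IS_MASS_NG: float = 400.0


class ValidationError(ValueError):
    """A domain invariant is violated by otherwise well-formed data."""


class SchemaError(ValueError):
    """An input file does not match the documented CSV schema."""


_PUNCT_RE = re.compile(r"[^a-z0-9]+")

# Spelling variants that must resolve to the same compound.  The salicylate
# ester is written both "methyl salicylate" and "menthyl salicylate" in the
# tea-aroma literature.
_NAME_ALIASES = {
    "menthylsalicylate": "methylsalicylate",
}


def normalize_name(name: str) -> str:
    """Case-insensitive compound-name key with punctuation stripped.

    ``"Phenylethyl Alcohol"`` and ``"phenylethyl-alcohol"`` map to the same
    key; known spelling variants are collapsed via an alias table.
    """
    key = _PUNCT_RE.sub("", name.lower())
    return _NAME_ALIASES.get(key, key)


@dataclass(frozen=True)
class CompoundRecord:
    """One catalog entry.

    Parameters
    ----------
    compound_id
        Stable key used in peak tables and matrices.
    name
        Human-readable compound name.
    chem_class
        One of :data:`CHEM_CLASSES`.
    odor_note
        Free-text aroma description (may be empty).
    odor_threshold_air
        Odor threshold in air, ng/g on the same basis as relative
        concentrations; ``None`` when unknown.  Must be positive if present.
    """

    compound_id: str
    name: str
    chem_class: str
    odor_note: str = ""
    odor_threshold_air: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"compound {self.compound_id!r}: unknown chemical class "
                f"{self.chem_class!r}; expected one of {CHEM_CLASSES}"
            )
        if self.odor_threshold_air is not None and not self.odor_threshold_air > 0:
            raise ValidationError(
                f"compound {self.compound_id!r}: odor_threshold_air must be "
                f"positive, got {self.odor_threshold_air!r}"
            )


class CompoundCatalog:
    """Ordered collection of :class:`CompoundRecord`, keyed by compound id."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self._records: Dict[str, CompoundRecord] = {}
        self._by_name: Dict[str, str] = {}
        for rec in records:
            if rec.compound_id in self._records:
                raise ValidationError(f"duplicate compound_id {rec.compound_id!r}")
            self._records[rec.compound_id] = rec
            self._by_name.setdefault(normalize_name(rec.name), rec.compound_id)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self._records.values())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._records

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        try:
            return self._records[compound_id]
        except KeyError:
            raise KeyError(f"unknown compound_id {compound_id!r}") from None

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(self._records)

    def find_by_name(self, name: str) -> CompoundRecord:
        """Look a compound up by (normalized) name."""
        key = normalize_name(name)
        if key not in self._by_name:
            raise KeyError(f"no compound named {name!r}")
        return self._records[self._by_name[key]]

    def by_class(self, chem_class: str) -> Tuple[CompoundRecord, ...]:
        return tuple(r for r in self if r.chem_class == chem_class)

    def class_counts(self) -> Dict[str, int]:
        counts = {c: 0 for c in CHEM_CLASSES}
        for rec in self:
            counts[rec.chem_class] += 1
        return counts


@dataclass
class InjectionRecord:
    """One GC-MS run of one tea sample.

    ``peak_areas`` maps compound id to raw (arbitrary-unit) peak area;
    ``is_peak_area`` is the internal-standard (ethyl decanoate) area in the
    same run.
    """

    sample_id: str
    group: str
    replicate: int
    dry_mass_g: float
    is_peak_area: float
    peak_areas: Dict[str, float]

    def validate(self, catalog: CompoundCatalog) -> None:
        if not self.dry_mass_g > 0:
            raise ValidationError(
                f"injection {self.sample_id}/r{self.replicate}: dry_mass_g must "
                f"be positive, got {self.dry_mass_g}"
            )
        if not self.is_peak_area > 0:
            raise ValidationError(
                f"injection {self.sample_id}/r{self.replicate}: internal-standard "
                f"peak area must be positive, got {self.is_peak_area}"
            )
        for cid, area in self.peak_areas.items():
            if cid not in catalog:
                raise ValidationError(
                    f"injection {self.sample_id}/r{self.replicate}: compound "
                    f"{cid!r} not in catalog"
                )
            if area < 0:
                raise ValidationError(
                    f"injection {self.sample_id}/r{self.replicate}: negative peak "
                    f"area {area} for compound {cid!r}"
                )


@dataclass
class PeakTable:
    """A full set of injections sharing one compound universe.

    ``is_mass_ng`` is the internal-standard mass added per injection
    (default 400 ng).
    """

    injections: List[InjectionRecord]
    catalog: CompoundCatalog
    is_mass_ng: float = DEFAULT_IS_MASS_NG

    def validate(self, group_labels: Optional[Sequence[str]] = None) -> None:
        """Check all type invariants; raise :class:`ValidationError` on failure."""
        if not self.is_mass_ng > 0:
            raise ValidationError(f"is_mass_ng must be positive, got {self.is_mass_ng}")
        universe = set(self.catalog.ids)
        offenders = []
        for inj in self.injections:
            inj.validate(self.catalog)
            if set(inj.peak_areas) - universe:
                raise ValidationError(
                    f"injection {inj.sample_id}/r{inj.replicate} uses compounds "
                    f"outside the shared universe"
                )
            if group_labels is not None and inj.group not in group_labels:
                offenders.append((inj.sample_id, inj.replicate, inj.group))
        if offenders:
            raise ValidationError(
                "group labels outside the configured set: "
                + ", ".join(f"{s}/r{r}: {g!r}" for s, r, g in offenders)
            )

    @property
    def groups(self) -> Tuple[str, ...]:
        """Group labels in order of first appearance."""
        seen: Dict[str, None] = {}
        for inj in self.injections:
            seen.setdefault(inj.group, None)
        return tuple(seen)

    @property
    def n_injections(self) -> int:
        return len(self.injections)


@dataclass
class RunConfig:
    """Analysis thresholds and tuning knobs for one pipeline run.

    Defaults follow the study conventions: markers are compounds with
    VIP > 1, aroma-active compounds have OAV > 1, model validation uses
    7-fold cross-validation and 200 label permutations, significance at
    p < 0.05 (strong at p < 0.01), and heat-map z-scores clip at +/-4.
    """

    group_labels: Tuple[str, ...] = DEFAULT_GROUPS
    vip_cutoff: float = 1.0
    oav_cutoff: float = 1.0
    cv_folds: int = 7
    n_permutations: int = 200
    alpha: float = 0.05
    strong_alpha: float = 0.01
    heat_clip: float = 4.0
    seed: int = 1

    def __post_init__(self) -> None:
        self.group_labels = tuple(self.group_labels)
        if not self.vip_cutoff > 0:
            raise ValidationError("vip_cutoff must be positive")
        if not self.oav_cutoff > 0:
            raise ValidationError("oav_cutoff must be positive")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be at least 2")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be at least 1")
        if not 0 < self.alpha < 1 or not 0 < self.strong_alpha < 1:
            raise ValidationError("alpha levels must lie in (0, 1)")
        if not self.heat_clip > 0:
            raise ValidationError("heat_clip must be positive")

    def to_dict(self) -> Dict[str, object]:
        return {
            "group_labels": list(self.group_labels),
            "vip_cutoff": self.vip_cutoff,
            "oav_cutoff": self.oav_cutoff,
            "cv_folds": self.cv_folds,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "strong_alpha": self.strong_alpha,
            "heat_clip": self.heat_clip,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]
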