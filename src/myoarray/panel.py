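"""Marker panel definitions for the energy-metabolism RPMA assay.

The default panel covers 19 proteins spanning glycogen degradation (PYGM),
glycolysis (GAPDH, PK, LDHA), the glycerol-phosphate shuttle (GPD1),
pyruvate oxidation (PDH), fatty-acid oxidation (CPT1M, HADHA), the Krebs
cycle (CS), the respiratory chain (NADHs9, SDH, COX1), oxidative
phosphorylation (aF1, bF1, IF1), oxidative-stress markers (ACO1, SOD2) and
structural normalizers (bActin, Hsp60), plus three derived bioenergetic
ratios: bF1/GAPDH, the BEC index ((bF1/Hsp60)/GAPDH) and bF1/LDHA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Compartment(str, Enum):
    MITOCHONDRIAL = "mitochondrial"
    CYTOPLASMIC = "cytoplasmic"


#: The 19 assayed proteins and their compartment.
DEFAULT_MARKERS: tuple[tuple[str, Compartment], ...] = (
    ("PDH", Compartment.MITOCHONDRIAL),
    ("SDH", Compartment.MITOCHONDRIAL),
    ("CS", Compartment.MITOCHONDRIAL),
    ("Hsp60", Compartment.MITOCHONDRIAL),
    ("CPT1M", Compartment.MITOCHONDRIAL),
    ("HADHA", Compartment.MITOCHONDRIAL),
    ("NADHs9", Compartment.MITOCHONDRIAL),
    ("COX1", Compartment.MITOCHONDRIAL),
    ("aF1", Compartment.MITOCHONDRIAL),
    ("bF1", Compartment.MITOCHONDRIAL),
    ("IF1", Compartment.MITOCHONDRIAL),
    ("SOD2", Compartment.MITOCHONDRIAL),
    ("bActin", Compartment.CYTOPLASMIC),
    ("GAPDH", Compartment.CYTOPLASMIC),
    ("PK", Compartment.CYTOPLASMIC),
    ("LDHA", Compartment.CYTOPLASMIC),
    ("GPD1", Compartment.CYTOPLASMIC),
    ("PYGM", Compartment.CYTOPLASMIC),
    ("ACO1", Compartment.CYTOPLASMIC),
)

#: Derived ratio name -> marker constituents (numerators..., denominator last
#: for the simple ratios; BEC is (bF1 / Hsp60) / GAPDH).
RATIO_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "bF1_GAPDH": ("bF1", "GAPDH"),
    "BEC": ("bF1", "Hsp60", "GAPDH"),
    "bF1_LDHA": ("bF1", "LDHA"),
}

#: Marker subsets used for the three published clustering comparisons.
CLUSTER_PRESETS: dict[str, dict] = {
    "mito_glycv": {
        "markers": ["NADHs9", "PYGM", "bF1_GAPDH"],
        "groups": ["CTR", "ComplexI", "GlycV"],
        "k": 3,
    },
    "dystrophies": {
        "markers": ["LDHA", "BEC", "PYGM"],
        "groups": ["CTR", "DMD", "BMD", "Xp21", "LGMD2C"],
        "k": 2,
    },
    "ncl": {
        "markers": ["PYGM", "GPD1", "bF1_LDHA"],
        "groups": ["CTR", "NCL"],
        "k": 2,
    },
}


@dataclass(frozen=True)
class MarkerPanel:
    """The assayed proteins plus the derived ratio columns.

    Invariants: marker names unique; every ratio constituent is an assayed
    marker.
    """

    markers: tuple[tuple[str, Compartment], ...] = DEFAULT_MARKERS
    derived_ratios: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(RATIO_DEFINITIONS)
    )

    def __post_init__(self) -> None:
        names = [name for name, _ in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        for ratio, parts in self.derived_ratios.items():
            missing = [p for p in parts if p not in names]
            if missing:
                raise ValueError(
                    f"ratio {ratio!r} references unknown markers: {missing}"
                )

    @property
    def marker_names(self) -> list[str]:
        return [name for name, _ in self.markers]

    @property
    def ratio_names(self) -> list[str]:
        return list(self.derived_ratios)

    @property
    def all_columns(self) -> list[str]:
        """Assayed markers followed by derived ratio columns."""
        return self.marker_names + self.ratio_names

    def compartment(self, marker: str) -> Compartment:
        for name, comp in self.markers:
            if name == marker:
                return comp
        raise KeyError(marker)


def default_panel() -> MarkerPanel:
    """The 19-protein panel with the three bioenergetic ratios."""
    return MarkerPanel()
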