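"""The CpG panel: 37 differentially methylated sites with gene and functional-class annotation.

The panel drives two things downstream: which columns of the cohort table are
treated as candidate mediators, and the functional-class colour strip under the
column dendrogram of the clustered frequency heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The eight functional classes used to annotate CpG sites in reports.
FUNCTIONAL_CLASSES: tuple[str, ...] = (
    "Cerebral/neuronal",
    "Growth/Development/Locomotion",
    "Metabolism",
    "Gene expression/DNA regulation/Epigenetic regulation",
    "Intra/intercellular Signaling/Transport",
    "Non-coding RNA/pseudogene",
    "Oncogenic/Apoptosis",
    "Intergenic",
)

PANEL_SIZE = 37

# Sites with published probe id / gene annotation. Functional-class labels for
# these genes are this package's own plausible assignment (class membership is
# only used for figure annotation, never for modelling).
_NAMED_SITES: list[tuple[str, str, str]] = [
    ("cg14172797", "PRKCA", "Cerebral/neuronal"),
    ("cg11047783", "KAT6B", "Gene expression/DNA regulation/Epigenetic regulation"),
    ("cg14109551", "CEP85L", "Cerebral/neuronal"),
    ("cg14450616", "PLD3", "Cerebral/neuronal"),
    ("cg26308668", "srGAP1", "Cerebral/neuronal"),
    ("cg14364797", "FNBP1", "Cerebral/neuronal"),
    ("cg22645359", "TCF7L2", "Intra/intercellular Signaling/Transport"),
    ("cg12928479", "NLRC5", "Gene expression/DNA regulation/Epigenetic regulation"),
    ("cg22076676", "THADA", "Oncogenic/Apoptosis"),
    ("cg01842756", "RNF217", "Oncogenic/Apoptosis"),
    ("cg16301196", "PLA2G15", "Metabolism"),
    ("cg07375256", "ZSCAN25", "Gene expression/DNA regulation/Epigenetic regulation"),
    ("cg26683792", "SLC35E1", "Intra/intercellular Signaling/Transport"),
]


@dataclass(frozen=True)
class CpGPanel:
    """A panel of CpG sites with gene symbols and functional classes.

    ``table`` has columns ``cpg_id``, ``gene``, ``functional_class`` and
    optionally ``placeholder`` (True for synthetic filler sites).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"cpg_id", "gene", "functional_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        ids = self.table["cpg_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate cpg_id entries: {dupes}")
        bad = set(self.table["functional_class"]) - set(FUNCTIONAL_CLASSES)
        if bad:
            raise ValueError(f"unknown functional classes: {sorted(bad)}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.table["cpg_id"])

    @property
    def classes(self) -> dict[str, str]:
        """Map cpg_id -> functional class."""
        return dict(zip(self.table["cpg_id"], self.table["functional_class"]))

    @property
    def genes(self) -> dict[str, str]:
        return dict(zip(self.table["cpg_id"], self.table["gene"]))

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CpGPanel":
        return cls(pd.read_csv(path))


def builtin_panel() -> CpGPanel:
    """The built-in 37-site panel.

    13 sites carry their published probe id and gene symbol. The remaining 24
    are synthetic placeholders (``cgSIM000xx``, marked ``placeholder=True``)
    whose gene field is either a synthetic symbol or "intergenic", with
    functional classes cycled over all eight classes so every class is
    represented in figure legends.
    """
    rows = [
        {"cpg_id": cid, "gene": gene, "functional_class": fc, "placeholder": False}
        for cid, gene, fc in _NAMED_SITES
    ]
    n_fill = PANEL_SIZE - len(rows)
    for k in range(n_fill):
        fc = FUNCTIONAL_CLASSES[k % len(FUNCTIONAL_CLASSES)]
        gene = "intergenic" if fc == "Intergenic" else f"SIMGENE{k + 1}"
        rows.append(
            {
                "cpg_id": f"cgSIM{k + 1:05d}",
                "gene": gene,
                "functional_class": fc,
                "placeholder": True,
            }
        )
    return CpGPanel(pd.DataFrame(rows))
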