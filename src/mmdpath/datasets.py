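"""Bundled study data: the public nutrimouse nutrigenomic dataset.

Forty mice (20 wild-type, 20 PPAR-deficient) were fed five diets (coc, fish,
lin, ref, sun; four mice per genotype x diet cell).  From liver, the study
measured expressions of 120 genes (nylon macroarray) and concentrations of 21
hepatic fatty acids (gas chromatography).  The copy shipped here was exported
as plain TSV from the dataset as distributed with the mixOmics R package
(Martin et al. nutrigenomic study); values are unchanged.

``CATABOLISM_GENES`` lists the fatty-acid catabolism pathway members used in
the worked analyses (the dataset spells one of them ``PMDCI``), and
``OMEGA3_LIPIDS`` the three long-chain omega-3 fatty acids integrated with
the gene block.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import GeneSet, OmicsBlock, SampleMetadata, load_block, load_metadata

__all__ = ["load_nutrimouse", "catabolism_gene_set", "omega3_lipid_set",
           "pathways_gmt_path", "CATABOLISM_GENES", "OMEGA3_LIPIDS"]

CATABOLISM_GENES: tuple[str, ...] = (
    "PECI", "PMDCI", "HPNCL", "AOX", "BIEN", "THIOL", "CACP", "CPT2",
    "Tpalpha", "Tpbeta", "mHMGCoAS", "CYP4A10", "CYP4A14", "ACBP",
    "L.FABP", "ACOTH", "PLTP",
)

OMEGA3_LIPIDS: tuple[str, ...] = ("C20.5n.3", "C22.5n.3", "C22.6n.3")


def _data_path(name: str) -> Path:
    return Path(resources.files("mmdpath") / "data" / name)


def load_nutrimouse() -> tuple[OmicsBlock, OmicsBlock, SampleMetadata]:
    """Load the bundled gene (40 x 120) and lipid (40 x 21) blocks + metadata."""
    genes = load_block(_data_path("nutrimouse_genes.tsv"), name="genes")
    lipids = load_block(_data_path("nutrimouse_lipids.tsv"), name="lipids")
    meta = load_metadata(_data_path("nutrimouse_meta.tsv"))
    return genes, lipids, meta


def catabolism_gene_set() -> GeneSet:
    """The fatty-acid catabolism pathway (17 genes)."""
    return GeneSet("catabolism", list(CATABOLISM_GENES))


def omega3_lipid_set() -> GeneSet:
    """The three long-chain omega-3 fatty acids (EPA, DPA, DHA)."""
    return GeneSet("omega3", list(OMEGA3_LIPIDS))


def pathways_gmt_path() -> Path:
    """Path to the bundled GMT file holding both feature sets."""
    return _data_path("pathways.gmt")
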