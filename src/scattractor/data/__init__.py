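"""Packaged gene-list fixtures for worked examples and tests.

The lists describe the APOD+DCN+LUM+ ASC/FAP stromal-progenitor signature
and related published fibroblast marker sets. ``asc_fap_core_signature``
carries the nine signature genes as stated in the literature. Files with
a ``_synthetic`` suffix are reconstructions: plausible marker lists built
to satisfy the documented relationships between the published lists (ten
genes shared between the ASC and FAP lists; a 12-gene pancreatic-cancer
chemo-resistance signature containing C7, CFD and PTGDS; the cluster
marker trios), not verbatim transcriptions of the original figures.
"""

from __future__ import annotations

from importlib import resources

from ..matrix_io import GeneList

__all__ = ["available_lists", "load_gene_list"]


def available_lists() -> list[str]:
    """Names (without extension) of all packaged gene lists."""
    pkg = resources.files(__package__)
    return sorted(
        p.name[:-4] for p in pkg.iterdir() if p.name.endswith(".txt")
    )


def load_gene_list(name: str) -> GeneList:
    """Load a packaged gene list by name (see :func:`available_lists`)."""
    pkg = resources.files(__package__)
    path = pkg / f"{name}.txt"
    if not path.is_file():
        raise KeyError(
            f"no packaged gene list {name!r}; available: {available_lists()}"
        )
    genes: list[str] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line and line not in genes:
            genes.append(line)
    return GeneList(name=name, genes=tuple(genes))
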