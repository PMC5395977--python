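"""Mitochondrial tRNA ninth-position (p9) site annotation.

The default annotation covers the 11 p9 positions on the mitochondrial
genome known to carry m1A/m1G methylation. Reference alleles are taken
from the packaged synthetic mitochondrial contig; when analysing real
data, load a site table whose ``ref_allele`` column matches the reference
the reads were aligned to (``read_sites_tsv``).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MITO_CONTIG = "chrM"
MITO_LENGTH = 16569

#: The 11 annotated p9 positions (1-based mitochondrial coordinates).
P9_POSITIONS = (585, 1610, 4271, 5520, 7526, 8303, 9999, 10413, 12174, 12246, 14734)

# tRNA names per position; tRNA-Glu (14734) lies on the light strand.
_TRNA_NAMES = {
    585: "MT-TF",
    1610: "MT-TV",
    4271: "MT-TI",
    5520: "MT-TW",
    7526: "MT-TD",
    8303: "MT-TK",
    9999: "MT-TG",
    10413: "MT-TR",
    12174: "MT-TH",
    12246: "MT-TS2",
    14734: "MT-TE",
}
_LIGHT_STRAND = {14734}

_BASES = ("A", "C", "G", "T")


@functools.lru_cache(maxsize=1)
def mito_reference() -> str:
    """Deterministic synthetic mitochondrial contig (16,569 bp).

    Generated from a fixed seed that is independent of any simulation
    seed, so site reference alleles are stable across all runs.
    """
    rng = np.random.default_rng(16569)
    idx = rng.integers(0, 4, size=MITO_LENGTH)
    return "".join(_BASES[i] for i in idx)


@dataclass(frozen=True)
class TrnaSite:
    """One annotated mt-tRNA p9 site.

    position is 1-based on the mitochondrial contig; strand is the strand
    the tRNA is transcribed from ('+' heavy, '-' light). ref_allele is the
    reference base at the position.
    """

    site_id: str
    position: int
    trna_name: str
    strand: str
    ref_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site {self.site_id}: position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.site_id}: strand must be '+' or '-'")
        if self.ref_allele not in _BASES:
            raise ValueError(f"site {self.site_id}: ref_allele must be one of A/C/G/T")

    @property
    def cleavage_position(self) -> int:
        """Genomic coordinate 9 bases upstream of p9 in tRNA orientation."""
        return self.position - 9 if self.strand == "+" else self.position + 9

    @property
    def control_position(self) -> int:
        """Control coordinate a further 9 bases upstream."""
        return self.position - 18 if self.strand == "+" else self.position + 18


def default_sites() -> list[TrnaSite]:
    """The default 11-site annotation on the synthetic reference."""
    ref = mito_reference()
    return [
        TrnaSite(
            site_id=f"p9_{pos}",
            position=pos,
            trna_name=_TRNA_NAMES[pos],
            strand="-" if pos in _LIGHT_STRAND else "+",
            ref_allele=ref[pos - 1],
        )
        for pos in P9_POSITIONS
    ]


def sites_to_frame(sites: Iterable[TrnaSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "position": s.position,
                "trna_name": s.trna_name,
                "strand": s.strand,
                "ref_allele": s.ref_allele,
            }
            for s in sites
        ]
    )


def write_sites_tsv(sites: Iterable[TrnaSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[TrnaSite]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    required = {"site_id", "position", "trna_name", "strand", "ref_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return [
        TrnaSite(
            site_id=row.site_id,
            position=int(row.position),
            trna_name=row.trna_name,
            strand=row.strand,
            ref_allele=row.ref_allele,
        )
        for row in df.itertuples()
    ]


def site_index(sites: Sequence[TrnaSite]) -> dict[str, TrnaSite]:
    return {s.site_id: s for s in sites}
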