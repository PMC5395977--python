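"""Convert filtered alignments into per-site allele counts and read-terminus counts.

Only properly paired, uniquely mapped primary alignments contribute;
"uniquely mapped" is operationalised as a MAPQ floor (default 30,
override for aligners that flag unique mappings differently). Base
quality filtering matches the pileup default (Q13). All coordinates in
the public API are 1-based inclusive; the SAM layer converts internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

from mtp9.sites import MITO_LENGTH, TrnaSite

BASES = ("A", "C", "G", "T")

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 13

#: reject reason codes, in the order the checks are applied
REASONS = ("malformed", "unmapped", "secondary", "supplementary", "duplicate", "pairing", "mapq")


@dataclass
class FilterParams:
    min_mapq: int = DEFAULT_MIN_MAPQ
    min_base_quality: int = DEFAULT_MIN_BASEQ
    require_proper_pair: bool = True
    exclude_duplicates: bool = True


def filter_read(
    read,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    require_proper_pair: bool = True,
    exclude_duplicates: bool = True,
) -> tuple[bool, str | None]:
    """Decide whether an alignment contributes to counting.

    Returns ``(True, None)`` to keep, else ``(False, reason)``. A record
    that cannot be interrogated yields ``(False, "malformed")`` rather
    than raising.
    """
    try:
        if read.is_unmapped:
            return False, "unmapped"
        if read.is_secondary:
            return False, "secondary"
        if read.is_supplementary:
            return False, "supplementary"
        if exclude_duplicates and read.is_duplicate:
            return False, "duplicate"
        if require_proper_pair and not read.is_proper_pair:
            return False, "pairing"
        if read.mapping_quality < min_mapq:
            return False, "mapq"
    except (AttributeError, TypeError, ValueError):
        return False, "malformed"
    return True, None


def _open_alignments(alignments) -> Iterator:
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def count_alleles(
    alignments,
    sites: Sequence[TrnaSite],
    min_base_quality: int = DEFAULT_MIN_BASEQ,
    sample_id: str = "sample",
    params: FilterParams | None = None,
    contig_length: int = MITO_LENGTH,
) -> pd.DataFrame:
    """Per-site A/C/G/T counts over filtered reads.

    Deletions and reference skips do not contribute (no query base);
    bases below ``min_base_quality`` are excluded. Returns one row per
    site: sample_id, site_id, count_A..count_T, depth.
    """
    if params is None:
        params = FilterParams(min_base_quality=min_base_quality)
    for site in sites:
        if site.position > contig_length:
            raise ValueError(
                f"site {site.site_id} at position {site.position} exceeds contig length {contig_length}"
            )
    by_pos0 = {s.position - 1: s.site_id for s in sites}
    counts = {s.site_id: dict.fromkeys(BASES, 0) for s in sites}
    lo = min(by_pos0) if by_pos0 else 0
    hi = max(by_pos0) if by_pos0 else 0

    for read in _open_alignments(alignments):
        keep, _ = filter_read(
            read,
            min_mapq=params.min_mapq,
            require_proper_pair=params.require_proper_pair,
            exclude_duplicates=params.exclude_duplicates,
        )
        if not keep:
            continue
        if read.reference_start > hi or read.reference_end is None or read.reference_end <= lo:
            continue
        seq = read.query_sequence
        quals = read.query_qualities
        if seq is None or quals is None:
            continue
        # matches_only drops deletions/skips (no query base) and soft clips
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            site_id = by_pos0.get(rpos)
            if site_id is None:
                continue
            if quals[qpos] < params.min_base_quality:
                continue
            base = seq[qpos].upper()
            if base in counts[site_id]:
                counts[site_id][base] += 1

    rows = []
    for site in sites:
        c = counts[site.site_id]
        rows.append(
            {
                "sample_id": sample_id,
                "site_id": site.site_id,
                "count_A": c["A"],
                "count_C": c["C"],
                "count_G": c["G"],
                "count_T": c["T"],
                "depth": sum(c.values()),
            }
        )
    return pd.DataFrame(rows)


def count_termini(
    alignments,
    positions: Iterable[int],
    sample_id: str = "sample",
    params: FilterParams | None = None,
    contig_length: int = MITO_LENGTH,
) -> pd.DataFrame:
    """Per-position read start/end/cover counts over filtered reads.

    A read "starts" at its first aligned reference base and "ends" at its
    last (soft-clipped bases are not aligned). A read covers a position
    when its aligned reference span [first, last] contains it; bases
    spanned by a deletion still count as covered, since coverage here
    measures reads crossing a boundary, not emitted bases.
    """
    if params is None:
        params = FilterParams()
    positions = sorted(set(int(p) for p in positions))
    for p in positions:
        if p < 1 or p > contig_length:
            raise ValueError(f"terminus position {p} outside contig [1, {contig_length}]")
    n_start = dict.fromkeys(positions, 0)
    n_end = dict.fromkeys(positions, 0)
    n_cover = dict.fromkeys(positions, 0)

    for read in _open_alignments(alignments):
        keep, _ = filter_read(
            read,
            min_mapq=params.min_mapq,
            require_proper_pair=params.require_proper_pair,
            exclude_duplicates=params.exclude_duplicates,
        )
        if not keep:
            continue
        if read.reference_end is None:
            continue
        first = read.reference_start + 1  # 1-based first aligned base
        last = read.reference_end  # reference_end is exclusive 0-based == inclusive 1-based
        if first in n_start:
            n_start[first] += 1
        if last in n_end:
            n_end[last] += 1
        for p in positions:
            if first <= p <= last:
                n_cover[p] += 1

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "position": positions,
            "n_start": [n_start[p] for p in positions],
            "n_end": [n_end[p] for p in positions],
            "n_cover": [n_cover[p] for p in positions],
        }
    )


def terminus_positions_for_sites(sites: Sequence[TrnaSite]) -> list[int]:
    """All positions needed downstream for cleavage rate and control."""
    pos: set[int] = set()
    for s in sites:
        c = s.cleavage_position
        ctrl = s.control_position
        step = 1 if s.strand == "+" else -1
        pos.update((c, c + step, ctrl, ctrl + step))
    return sorted(p for p in pos if p >= 1)
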