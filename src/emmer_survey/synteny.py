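"""Link-based synteny: ribbons, gene-density tracks, translocation flags.

Any query placed at a unique best location in both genomes contributes one
link between the two positions.  Links are bundled into ribbons by binning
their midpoints into fixed windows on both sides (published scale: more than
200 links per 1-Mb interval; both are configurable, and the strictly-greater
rule is preserved at any threshold).  Bundled ribbons joining chromosomes
outside the expected correspondence map are flagged as translocation-like
signals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .scaffolds import Placement

DEFAULT_WINDOW = 1_000_000
DEFAULT_MIN_LINKS = 200  # bundled iff strictly more links than this
DEFAULT_DENSITY_WINDOW = 500_000


@dataclass(frozen=True)
class SyntenyLink:
    query_id: str
    chromosome1: str
    start1: int
    end1: int
    chromosome2: str
    start2: int
    end2: int


@dataclass(frozen=True)
class Ribbon:
    chromosome1: str
    window1: int  # bin index on genome 1
    chromosome2: str
    window2: int
    link_count: int
    bundled: bool


def _unique_best(placements: Iterable[Placement]) -> dict[str, Placement]:
    """Unique best placement per query: the top score must be strict."""
    by_query: dict[str, list[Placement]] = {}
    for p in placements:
        by_query.setdefault(p.query_id, []).append(p)
    out = {}
    for q, ps in by_query.items():
        if len(ps) == 1:
            out[q] = ps[0]
            continue
        ps.sort(key=lambda p: -p.score)
        if ps[0].score > ps[1].score:
            out[q] = ps[0]
    return out


def build_links(
    placements1: Iterable[Placement], placements2: Iterable[Placement]
) -> list[SyntenyLink]:
    """One link per query with a unique best placement in each genome."""
    best1 = _unique_best(placements1)
    best2 = _unique_best(placements2)
    links = []
    for q in sorted(set(best1) & set(best2)):
        p1, p2 = best1[q], best2[q]
        links.append(
            SyntenyLink(q, p1.reference_chromosome, p1.start, p1.end,
                        p2.reference_chromosome, p2.start, p2.end)
        )
    return links


def bundle_ribbons(
    links: Iterable[SyntenyLink],
    window: int = DEFAULT_WINDOW,
    min_links: int = DEFAULT_MIN_LINKS,
) -> list[Ribbon]:
    """Assign each link to the window pair containing its midpoints.

    Ribbon counts sum to the link count by construction; a ribbon is bundled
    iff its count strictly exceeds ``min_links``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts: Counter[tuple[str, int, str, int]] = Counter()
    for link in links:
        mid1 = (link.start1 + link.end1) // 2
        mid2 = (link.start2 + link.end2) // 2
        counts[(link.chromosome1, mid1 // window, link.chromosome2, mid2 // window)] += 1
    return [
        Ribbon(c1, w1, c2, w2, n, n > min_links)
        for (c1, w1, c2, w2), n in sorted(counts.items())
    ]


def gene_density(
    positions: Iterable[int],
    chromosome_length: int,
    window: int = DEFAULT_DENSITY_WINDOW,
) -> list[int]:
    """Per-window gene counts (half-open bins; a boundary position belongs to
    the right-hand window).  Counts sum to the number of genes."""
    if window <= 0:
        raise ValueError("window must be positive")
    n_bins = max(1, -(-chromosome_length // window))
    track = [0] * n_bins
    for pos in positions:
        if not 0 <= pos < chromosome_length:
            raise ValueError(f"gene position {pos} outside chromosome")
        track[pos // window] += 1
    return track


def flag_interchromosomal(
    ribbons: Iterable[Ribbon],
    expected_map: Mapping[str, Sequence[str] | str],
) -> list[Ribbon]:
    """Bundled ribbons whose chromosome pair is not an expected correspondence."""
    flags = []
    for r in ribbons:
        if not r.bundled:
            continue
        expected = expected_map.get(r.chromosome1, ())
        if isinstance(expected, str):
            expected = (expected,)
        if r.chromosome2 not in expected:
            flags.append(r)
    return flags


# -- IO ----------------------------------------------------------------------


def write_links_tsv(links: Iterable[SyntenyLink], path) -> None:
    """Circos-style link table: chr, start, end, chr, start, end, query."""
    with open(path, "w") as fh:
        for l in links:
            fh.write(
                f"{l.chromosome1}\t{l.start1}\t{l.end1}"
                f"\t{l.chromosome2}\t{l.start2}\t{l.end2}\t{l.query_id}\n"
            )


def write_ribbons_tsv(ribbons: Iterable[Ribbon], path, window: int = DEFAULT_WINDOW) -> None:
    with open(path, "w") as fh:
        for r in ribbons:
            fh.write(
                f"{r.chromosome1}\t{r.window1 * window}\t{(r.window1 + 1) * window}"
                f"\t{r.chromosome2}\t{r.window2 * window}\t{(r.window2 + 1) * window}"
                f"\t{r.link_count}\t{int(r.bundled)}\n"
            )


def write_density_bedgraph(
    tracks: Mapping[str, Sequence[int]], path, window: int = DEFAULT_DENSITY_WINDOW
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            for i, count in enumerate(tracks[chrom]):
                fh.write(f"{chrom}\t{i * window}\t{(i + 1) * window}\t{count}\n")
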