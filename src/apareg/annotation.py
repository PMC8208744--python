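"""Transcript models, polyadenylation sites and short/long 3'UTR regions.

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted on read.  A polyadenylation *site* is a single
boundary coordinate: for a 1-bp BED record [s, s+1) the site coordinate is
``s``.  In transcript orientation the 3'UTR runs from the annotated CDS end
to the transcript end; a proximal site splits it into the short region
(CDS end -> proximal site) and the long region (proximal site -> distal
site, the transcript's 3'-most site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript reduced to what region pairing needs.

    ``cds_end`` and ``tx_end`` are half-open boundary coordinates: on the
    '+' strand the 3'UTR is [cds_end, tx_end), on the '-' strand it is
    [tx_end, cds_end).  ``exons`` are genomic half-open intervals used to
    restrict regions to exonic bases in multi-exon UTRs; empty means the
    UTR is treated as a single contiguous block.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_end: int
    tx_end: int
    exons: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.cds_end < self.tx_end:
            raise ValueError(
                f"{self.transcript_id}: '+' strand requires cds_end < tx_end "
                f"({self.cds_end} >= {self.tx_end})"
            )
        if self.strand == "-" and not self.cds_end > self.tx_end:
            raise ValueError(
                f"{self.transcript_id}: '-' strand requires cds_end > tx_end "
                f"({self.cds_end} <= {self.tx_end})"
            )

    @property
    def utr3_interval(self) -> Interval:
        """Genomic half-open span of the 3'UTR."""
        if self.strand == "+":
            return (self.cds_end, self.tx_end)
        return (self.tx_end, self.cds_end)

    def utr3_blocks(self) -> list[Interval]:
        """3'UTR restricted to annotated exons (whole span if no exons)."""
        return _restrict_to_exons(self.utr3_interval, self.exons)


@dataclass(frozen=True)
class PolyASite:
    chrom: str
    position: int
    strand: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("site position must be >= 0")


@dataclass(frozen=True)
class RegionPair:
    """One proximal/distal site pair with derived short and long regions.

    ``short_region`` and ``long_region`` are genomic half-open spans that
    abut exactly at the proximal site; ``short_blocks``/``long_blocks`` are
    the exon-restricted sub-intervals actually used for read counting.
    """

    transcript_id: str
    chrom: str
    strand: str
    proximal_site: PolyASite
    distal_site: PolyASite
    short_region: Interval
    long_region: Interval
    short_blocks: tuple[Interval, ...] = ()
    long_blocks: tuple[Interval, ...] = ()
    name: str | None = None  # explicit id; default derives from coordinates

    @property
    def pair_id(self) -> str:
        if self.name is not None:
            return self.name
        return f"{self.transcript_id}:{self.proximal_site.position}-{self.distal_site.position}"

    @property
    def span(self) -> Interval:
        lo = min(self.short_region[0], self.long_region[0])
        hi = max(self.short_region[1], self.long_region[1])
        return (lo, hi)


def _restrict_to_exons(span: Interval, exons: tuple[Interval, ...]) -> list[Interval]:
    if not exons:
        return [span]
    lo, hi = span
    out = []
    for s, e in sorted(exons):
        a, b = max(s, lo), min(e, hi)
        if a < b:
            out.append((a, b))
    return out


def derive_regions(
    transcript: TranscriptModel, proximal: PolyASite, distal: PolyASite
) -> RegionPair:
    """Build the short and long regions for one proximal/distal site pair.

    The proximal site must fall strictly between the CDS end and the distal
    site in transcript orientation; a zero-length region is rejected.
    """
    p, d, c = proximal.position, distal.position, transcript.cds_end
    if transcript.strand == "+":
        ok = c < p < d
        short: Interval = (c, p)
        long: Interval = (p, d)
    else:
        ok = c > p > d
        short = (p, c)
        long = (d, p)
    if not ok:
        raise ValueError(
            f"{transcript.transcript_id}: proximal site {p} must lie strictly "
            f"between cds_end {c} and distal site {d} on strand {transcript.strand}"
        )
    short_blocks = tuple(_restrict_to_exons(short, transcript.exons))
    long_blocks = tuple(_restrict_to_exons(long, transcript.exons))
    if not short_blocks or not long_blocks:
        raise ValueError(
            f"{transcript.transcript_id}: region with no exonic bases "
            f"(short={short}, long={long})"
        )
    return RegionPair(
        transcript_id=transcript.transcript_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        proximal_site=proximal,
        distal_site=distal,
        short_region=short,
        long_region=long,
        short_blocks=short_blocks,
        long_blocks=long_blocks,
    )


def pair_sites(
    transcript: TranscriptModel,
    sites: list[PolyASite],
    *,
    accept_tx_end_as_distal: bool = False,
    warnings: list[str] | None = None,
) -> list[RegionPair]:
    """Form all proximal/distal pairs for one transcript.

    The single 3'-most site is the distal site of every pair; each other
    site appears as proximal in exactly one pair, so k distinct usable
    sites yield k-1 pairs.  Sites outside the 3'UTR are skipped with a
    warning record; duplicate positions are collapsed.  When
    ``accept_tx_end_as_distal`` is set, the annotated transcript end is
    added as a distal site if no provided site coincides with it.
    """
    lo, hi = transcript.utr3_interval
    positions: list[int] = []
    seen: set[int] = set()
    for s in sites:
        if s.chrom != transcript.chrom or s.strand != transcript.strand:
            continue
        if not (lo <= s.position <= hi):
            msg = (
                f"{transcript.transcript_id}: site {s.chrom}:{s.position}"
                f"({s.strand}) outside 3'UTR [{lo},{hi}] - skipped"
            )
            log.warning(msg)
            if warnings is not None:
                warnings.append(msg)
            continue
        if s.position in seen:
            continue
        seen.add(s.position)
        positions.append(s.position)

    if accept_tx_end_as_distal and transcript.tx_end not in seen:
        positions.append(transcript.tx_end)

    # transcript orientation: ascending on '+', descending on '-'
    positions.sort(reverse=(transcript.strand == "-"))
    # cds_end itself cannot serve as a proximal site (degenerate short region)
    usable = [p for p in positions if p != transcript.cds_end]
    if len(usable) < 2:
        return []
    distal_pos = usable[-1]
    distal = PolyASite(transcript.chrom, distal_pos, transcript.strand,
                       transcript.transcript_id)
    pairs = []
    for p in usable[:-1]:
        prox = PolyASite(transcript.chrom, p, transcript.strand,
                         transcript.transcript_id)
        try:
            pairs.append(derive_regions(transcript, prox, distal))
        except ValueError as exc:
            log.warning(str(exc))
            if warnings is not None:
                warnings.append(str(exc))
    return pairs


def build_region_pairs(
    transcripts: list[TranscriptModel],
    sites: list[PolyASite],
    *,
    accept_tx_end_as_distal: bool = False,
    warnings: list[str] | None = None,
) -> list[RegionPair]:
    """Pair every transcript with the sites overlapping its 3'UTR.

    Sites carrying a ``transcript_id`` are matched by id; unassociated
    sites are matched to any same-strand transcript whose 3'UTR contains
    them.
    """
    pairs: list[RegionPair] = []
    for tx in transcripts:
        lo, hi = tx.utr3_interval
        mine = [
            s for s in sites
            if (s.transcript_id == tx.transcript_id)
            or (s.transcript_id is None and s.chrom == tx.chrom
                and s.strand == tx.strand and lo <= s.position <= hi)
        ]
        pairs.extend(
            pair_sites(tx, mine, accept_tx_end_as_distal=accept_tx_end_as_distal,
                       warnings=warnings)
        )
    return pairs


# ---------------------------------------------------------------------------
# I/O


def read_sites_bed(path: str) -> list[PolyASite]:
    """Read polyadenylation sites from BED (>=3 columns; col 4 optionally a
    transcript id, col 6 the strand; missing strand defaults to '+')."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start = f[0], int(f[1])
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else None
            strand = f[5] if len(f) > 5 else "+"
            sites.append(PolyASite(chrom, start, strand, name))
    return sites


def read_transcripts_bed12(path: str) -> list[TranscriptModel]:
    """Read transcript models from BED12.

    ``thickStart``/``thickEnd`` delimit the CDS; block fields give exons.
    The name column is ``transcript_id`` or ``transcript_id|gene_id``.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}: {line[:80]}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            tid, _, gid = name.partition("|")
            cds_end = thick_end if strand == "+" else thick_start
            tx_end = end if strand == "+" else start
            out.append(
                TranscriptModel(tid, gid or tid, chrom, strand, cds_end, tx_end, exons)
            )
    return out


def read_transcripts_gtf(path: str) -> list[TranscriptModel]:
    """Read transcript models from GTF via gffutils (1-based closed
    coordinates converted to 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    out = []
    for tx in db.features_of_type("transcript"):
        tid = tx.attributes.get("transcript_id", [tx.id])[0]
        gid = tx.attributes.get("gene_id", [tid])[0]
        cds = list(db.children(tx, featuretype="CDS"))
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(tx, featuretype="exon"))
        )
        if not cds:
            continue  # non-coding: no CDS end to anchor the 3'UTR
        if tx.strand == "+":
            cds_end = max(c.end for c in cds)  # half-open end
            tx_end = tx.end
        else:
            cds_end = min(c.start - 1 for c in cds)
            tx_end = tx.start - 1
        out.append(
            TranscriptModel(tid, gid, tx.seqid, tx.strand, cds_end, tx_end, exons)
        )
    return out


def write_pairs_tsv(pairs: list[RegionPair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pair_id\ttranscript_id\tchrom\tstrand\tproximal\tdistal\t"
            "short_start\tshort_end\tlong_start\tlong_end\n"
        )
        for p in pairs:
            fh.write(
                f"{p.pair_id}\t{p.transcript_id}\t{p.chrom}\t{p.strand}\t"
                f"{p.proximal_site.position}\t{p.distal_site.position}\t"
                f"{p.short_region[0]}\t{p.short_region[1]}\t"
                f"{p.long_region[0]}\t{p.long_region[1]}\n"
            )
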