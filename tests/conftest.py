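import numpy as np
import pysam
import pytest

from apareg.annotation import PolyASite, RegionPair, TranscriptModel, derive_regions


@pytest.fixture
def plus_transcript() -> TranscriptModel:
    return TranscriptModel("txP", "geneP", "chr1", "+", 1000, 2000,
                           exons=((0, 2000),))


@pytest.fixture
def minus_transcript() -> TranscriptModel:
    return TranscriptModel("txM", "geneM", "chr1", "-", 2000, 1000,
                           exons=((1000, 2500),))


@pytest.fixture
def plus_pair(plus_transcript) -> RegionPair:
    return derive_regions(
        plus_transcript,
        PolyASite("chr1", 1400, "+", "txP"),
        PolyASite("chr1", 2000, "+", "txP"),
    )


def write_sam(path, reads, chrom="chr1", length=5000):
    """Write a minimal single-contig SAM; reads are (name, pos, cigar) or
    (name, pos, cigar, flag) tuples, positions 0-based."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for entry in sorted(reads, key=lambda t: t[1]):
            name, pos, cigar = entry[:3]
            flag = entry[3] if len(entry) > 3 else 0
            a = pysam.AlignedSegment()
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = "A" * a.infer_query_length()
            out.write(a)
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
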