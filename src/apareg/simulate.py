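"""Synthetic differential-APA datasets with known truth.

The generator works at the count level: for pair i and sample j a total
3'UTR depth T_ij is drawn negative-binomial (mean 200, dispersion 0.3 by
default, i.e. var = mu + 0.3 mu^2, emulating expression variability across
replicates), and the long-region count is Binomial(T_ij, p_ij) with

    logit(p_ij) = logit(p0) + log(f_cond) * I[group 2] + sum_c log(f_c) * I[level]

so effect sizes are odds fold changes on the long-isoform proportion,
additive on the logit scale and hence consistent with both fitted models.
A truth ledger labels each pair 'null', 'condition-APA' (nonzero condition
effect) or 'covariate-APA' (only a nuisance covariate moves the ratio --
null with respect to the condition).  Miniature SAM fixtures with exactly
matching counts make the counting layer testable end to end.

All randomness flows from the single seed in the config.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import PolyASite, RegionPair, TranscriptModel


@dataclass
class CovariateSpec:
    """A categorical nuisance covariate.

    ``effects`` maps non-reference levels to odds fold changes on the
    long-isoform proportion; ``assignment`` lists one level per sample
    (group 1 samples first), enabling imbalanced designs.
    ``frac_affected`` is the fraction of pairs whose ratio responds to
    the covariate.
    """

    name: str
    levels: tuple[str, ...]
    effects: dict[str, float]
    assignment: tuple[str, ...]
    frac_affected: float = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    effect is an odds fold change between conditions applied to the
    ``frac_apa`` first pairs; effect 1.0 means no condition-driven APA
    anywhere.
    """

    n_pairs: int = 300
    frac_apa: float = 0.0
    n_per_group: tuple[int, int] = (10, 10)
    p0: float = 0.2
    effect: float = 1.0
    covariates: tuple[CovariateSpec, ...] = ()
    nb_mean: float = 200.0
    nb_dispersion: float = 0.3
    expression_levels: tuple[float, ...] | None = None  # per-pair NB means
    # biological replicate variability of the isoform proportion: SD of a
    # per-pair-per-sample Gaussian added on the logit scale (0 = counts
    # are exactly binomial given the totals)
    prop_logit_sd: float = 0.0
    short_len: int = 500
    long_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("baseline proportion p0 must be in (0,1)")
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 samples per group")
        if not 0 <= self.frac_apa <= 1:
            raise ValueError("frac_apa must be in [0,1]")
        if self.effect <= 0:
            raise ValueError("effect (odds fold change) must be positive")
        if self.nb_mean <= 0 or self.nb_dispersion < 0:
            raise ValueError("invalid negative-binomial parameters")


def odds_fold_change_for_proportion_fc(prop_fc: float, p0: float) -> float:
    """Odds fold change giving a target proportion fold change at p0.

    Solves odds(p0 * prop_fc) / odds(p0); the target proportion must stay
    below 1.
    """
    p1 = p0 * prop_fc
    if not 0 < p1 < 1:
        raise ValueError(f"target proportion {p1} outside (0,1)")
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame  # pair_id, transcript_id, truth, cond_logodds
    config: SimulationConfig
    sam_paths: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.counts.to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t", index=False)
        self.samples.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)
        self.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
             size) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson when
    dispersion is 0)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def simulate_counts(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one count-level dataset per the config.

    The first ``round(frac_apa * n_pairs)`` pairs carry the condition
    effect; covariate effects (if any) hit the first
    ``round(frac_affected * n_pairs)`` pairs and label otherwise-null
    pairs 'covariate-APA'.
    """
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.n_per_group
    n = n1 + n2
    sample_ids = [f"s{i+1:02d}" for i in range(n)]
    group = np.array(["g1"] * n1 + ["g2"] * n2)
    samples = pd.DataFrame({"sample_id": sample_ids, "group": group})
    # condition indicator consistent with build_design (levels sorted, second=1)
    levels = sorted(set(group))
    cond = (group == levels[1]).astype(float)

    for cov in cfg.covariates:
        if len(cov.assignment) != n:
            raise ValueError(
                f"covariate {cov.name}: assignment length {len(cov.assignment)} "
                f"!= number of samples {n}"
            )
        samples[cov.name] = list(cov.assignment)

    n_apa = int(round(cfg.frac_apa * cfg.n_pairs)) if cfg.effect != 1.0 else 0
    b_cond = np.zeros(cfg.n_pairs)
    b_cond[:n_apa] = np.log(cfg.effect)

    eta = np.full((cfg.n_pairs, n), logit(cfg.p0))
    eta += b_cond[:, None] * cond[None, :]

    cov_affected = np.zeros(cfg.n_pairs, dtype=bool)
    for cov in cfg.covariates:
        m = int(round(cov.frac_affected * cfg.n_pairs))
        affected = np.zeros(cfg.n_pairs, dtype=bool)
        affected[:m] = True
        shift = np.array([np.log(cov.effects.get(a, 1.0)) for a in cov.assignment])
        if np.any(shift != 0):
            cov_affected |= affected
        eta += affected[:, None] * shift[None, :]

    means = (np.asarray(cfg.expression_levels, dtype=float)
             if cfg.expression_levels is not None
             else np.full(cfg.n_pairs, cfg.nb_mean))
    if means.size != cfg.n_pairs:
        raise ValueError("expression_levels must give one mean per pair")

    totals = _nb_draw(rng, means[:, None], cfg.nb_dispersion, (cfg.n_pairs, n))
    if cfg.prop_logit_sd > 0:
        eta = eta + rng.normal(0.0, cfg.prop_logit_sd, size=eta.shape)
    p = expit(eta)
    n_long = rng.binomial(totals, p)
    n_short = totals - n_long

    pair_ids = [f"pair{i+1:04d}" for i in range(cfg.n_pairs)]
    counts = pd.DataFrame({
        "pair_id": np.repeat(pair_ids, n),
        "transcript_id": np.repeat([f"tx{i+1:04d}" for i in range(cfg.n_pairs)], n),
        "sample_id": np.tile(sample_ids, cfg.n_pairs),
        "n_short": n_short.ravel(),
        "n_long": n_long.ravel(),
    })

    label = np.where(b_cond != 0, "condition-APA",
                     np.where(cov_affected, "covariate-APA", "null"))
    truth = pd.DataFrame({
        "pair_id": pair_ids,
        "transcript_id": [f"tx{i+1:04d}" for i in range(cfg.n_pairs)],
        "truth": label,
        "cond_logodds": b_cond,
    })
    return SimulatedDataset(counts, samples, truth, cfg)


def simulate_imbalanced(cfg: SimulationConfig | None = None, *,
                        sex_effect: float = 0.25,
                        males_per_group: tuple[int, int] = (4, 1),
                        seed: int = 0) -> SimulatedDataset:
    """Imbalanced-covariate scenario: only sex drives the ratio.

    Sex is unevenly split across conditions (default 4 males / 1 female in
    group 1 vs 1 male / 4 females in group 2 at n=5/group), the condition
    effect is zero, and males carry an odds fold change ``sex_effect`` on
    the long-isoform proportion (< 1: relatively higher short-region
    expression).  A condition-only model misattributes the covariate
    effect to the condition; including sex in the design removes it.
    """
    if cfg is None:
        cfg = SimulationConfig(n_pairs=200, n_per_group=(5, 5), seed=seed)
    n1, n2 = cfg.n_per_group
    m1, m2 = males_per_group
    if m1 > n1 or m2 > n2:
        raise ValueError("more males requested than samples in a group")
    assignment = tuple(["M"] * m1 + ["F"] * (n1 - m1) + ["M"] * m2 + ["F"] * (n2 - m2))
    sex = CovariateSpec(name="sex", levels=("F", "M"),
                        effects={"M": sex_effect}, assignment=assignment)
    cfg = replace(cfg, effect=1.0, frac_apa=0.0,
                  covariates=cfg.covariates + (sex,))
    return simulate_counts(cfg)


# ---------------------------------------------------------------------------
# Read-level fixtures


def region_pairs_for_dataset(dataset: SimulatedDataset, *, cds_len: int = 100
                             ) -> list[RegionPair]:
    """One single-exon transcript per pair, each on its own contig."""
    from .annotation import derive_regions

    from dataclasses import replace as _dc_replace

    cfg = dataset.config
    pairs = []
    for i, pair_id in enumerate(dataset.truth["pair_id"]):
        tid = dataset.truth["transcript_id"].iloc[i]
        chrom = f"chr_{pair_id}"
        cds_end = cds_len
        proximal = cds_end + cfg.short_len
        distal = proximal + cfg.long_len
        tx = TranscriptModel(tid, tid, chrom, "+", cds_end, distal,
                             exons=((0, distal),))
        p = derive_regions(tx, PolyASite(chrom, proximal, "+", tid),
                           PolyASite(chrom, distal, "+", tid))
        pairs.append(_dc_replace(p, name=str(pair_id)))
    return pairs


def _even_positions(start: int, end: int, read_length: int, k: int) -> list[int]:
    """k deterministic start positions with reads fully inside [start, end)."""
    last = end - read_length
    if last < start:
        raise ValueError(
            f"read length {read_length} exceeds region length {end - start}"
        )
    if k <= 1:
        return [start] * k
    return [start + round(i * (last - start) / (k - 1)) for i in range(k)]


def write_sam_fixture(dataset: SimulatedDataset, out_dir: str, *,
                      read_length: int = 50, cds_len: int = 100
                      ) -> list[RegionPair]:
    """Emit per-sample SAM files whose counts reproduce the dataset exactly.

    Each pair lives on its own contig with a single-exon transcript;
    short-region reads lie fully inside the short region and long-region
    reads fully inside the long region, evenly spaced.  Also writes the
    matching BED12 annotation, polyA-site BED, counts, sample sheet and
    truth tables.  Returns the region pairs for round-trip counting.
    """
    import pysam

    os.makedirs(out_dir, exist_ok=True)
    pairs = region_pairs_for_dataset(dataset, cds_len=cds_len)
    cfg = dataset.config
    contig_len = cds_len + cfg.short_len + cfg.long_len + 10
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": p.chrom, "LN": contig_len} for p in pairs],
    }
    counts = dataset.counts.set_index(["pair_id", "sample_id"])
    sam_paths = {}
    for sample_id in dataset.samples["sample_id"]:
        path = os.path.join(out_dir, f"{sample_id}.sam")
        with pysam.AlignmentFile(path, "w", header=dict(header)) as out:
            for p in pairs:
                row = counts.loc[(p.pair_id, sample_id)]
                placements = (
                    list(zip(_even_positions(*p.short_region, read_length,
                                             int(row["n_short"])),
                             ["S"] * int(row["n_short"])))
                    + list(zip(_even_positions(*p.long_region, read_length,
                                               int(row["n_long"])),
                               ["L"] * int(row["n_long"])))
                )
                placements.sort(key=lambda t: t[0])
                for j, (pos, tag) in enumerate(placements):
                    a = pysam.AlignedSegment()
                    a.query_name = f"{p.pair_id}.{sample_id}.{tag}{j}"
                    a.query_sequence = "A" * read_length
                    a.flag = 0
                    a.reference_id = out.get_tid(p.chrom)
                    a.reference_start = pos
                    a.mapping_quality = 60
                    a.cigar = [(0, read_length)]
                    out.write(a)
        sam_paths[sample_id] = path
    dataset.sam_paths = sam_paths
    dataset.write(out_dir)
    _write_fixture_annotation(pairs, contig_len, cds_len, out_dir)
    return pairs


def _write_fixture_annotation(pairs: list[RegionPair], contig_len: int,
                              cds_len: int, out_dir: str) -> None:
    with open(os.path.join(out_dir, "transcripts.bed12"), "w") as bed12, \
         open(os.path.join(out_dir, "sites.bed"), "w") as sites:
        for p in pairs:
            tx_end = p.long_region[1]
            bed12.write(
                f"{p.chrom}\t0\t{tx_end}\t{p.transcript_id}\t0\t+\t0\t{cds_len}"
                f"\t0\t1\t{tx_end}\t0\n"
            )
            for pos in (p.proximal_site.position, p.distal_site.position):
                sites.write(f"{p.chrom}\t{pos}\t{pos + 1}\t{p.transcript_id}\t0\t+\n")
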