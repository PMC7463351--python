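"""Seeded negative-binomial count simulator emulating the study design.

The generator mimics a common-garden transcriptome experiment: three
elevational zones (lowland, midland, highland) x five landraces per zone x
three field blocks = 45 libraries.  Counts for gene i in sample j are

    K_ij ~ NB(mean = s_j * mu_i * 2^(zone effect + block effect), alpha)

with log-normal baseline means mu_i, log-normal size factors s_j, per-gene
Gaussian block effects, and planted zone effects.  A tunable enrichment
factor phi >= 1 multiplies a candidate gene's probability of being
differentially expressed, so the enrichment stage has a known truth to
recover.  Candidate genes draw their baselines from a lower-mean
distribution than the background, which makes expression-matched
subsampling a real correction rather than a no-op.

Everything is reproducible from the single seed in :class:`SimConfig`;
per-stage RNG streams are derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, SampleInfo, ZONES


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real design: 45 libraries, ~12,000 expressed
    background genes, a 190-gene candidate set.  ``de_fraction`` is the
    probability a background gene carries a planted zone effect;
    candidates use ``min(1, enrichment_factor * de_fraction)``.  Planted
    log2 fold changes are Normal(0, log2fc_sd) truncated away from
    (-min_abs_log2fc, +min_abs_log2fc).
    """

    n_background_genes: int = 12000
    n_candidate_genes: int = 190
    landraces_per_zone: int = 5
    n_blocks: int = 3
    mean_log_mu: float = 4.0          # natural-log baseline mean (~55 counts)
    sd_log_mu: float = 2.0
    candidate_mean_log_mu: float = 2.5  # candidates sit lower (~12 counts)
    dispersion: float = 0.1
    de_fraction: float = 0.1
    log2fc_sd: float = 1.5
    min_abs_log2fc: float = 0.5
    enrichment_factor: float = 1.0    # phi: candidate DE-probability multiplier
    block_sd: float = 0.2             # per-gene log2 block effect sd
    size_factor_sd: float = 0.3       # log-normal sd of library depths
    # zone-pattern mixture for DE genes: highland-specific, shared
    # highland+midland, midland-specific (sums to 1)
    p_highland_only: float = 0.4
    p_shared: float = 0.4
    p_midland_only: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_background_genes < 1 or self.n_candidate_genes < 1:
            raise SimulationError("gene counts must be positive")
        if self.enrichment_factor < 1:
            raise SimulationError("enrichment_factor must be >= 1")
        if not 0 <= self.de_fraction <= 1:
            raise SimulationError("de_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.min_abs_log2fc < 0 or self.log2fc_sd <= 0:
            raise SimulationError("invalid log2fc distribution")
        pats = self.p_highland_only + self.p_shared + self.p_midland_only
        if abs(pats - 1.0) > 1e-9:
            raise SimulationError("zone-pattern probabilities must sum to 1")
        if self.landraces_per_zone < 1 or self.n_blocks < 1:
            raise SimulationError("design must have >= 1 landrace and block")


@dataclass
class SyntheticBundle:
    """Everything one simulation run produces."""

    counts: CountMatrix
    candidates: GeneSet
    background: GeneSet
    truth: pd.DataFrame


def _truncated_normal_lfc(rng, n, sd, min_abs):
    """Normal(0, sd) conditioned on |x| >= min_abs, by vectorized rejection."""
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(0.0, sd, size=remaining.size)
        ok = np.abs(draw) >= min_abs
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _nb_sample(rng, mean, alpha):
    """NB draws with mean/dispersion parameterization; alpha=0 is Poisson."""
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate(config: SimConfig) -> SyntheticBundle:
    """Generate counts, metadata, gene lists and ground truth."""
    config.validate()
    root = np.random.default_rng(config.seed)
    # deterministic per-stage streams
    rng_mu, rng_de, rng_block, rng_sf, rng_counts = (
        np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=5)
    )

    n_bg, n_cand = config.n_background_genes, config.n_candidate_genes
    n_genes = n_bg + n_cand
    gene_ids = [f"BG{i:05d}" for i in range(n_bg)] + [
        f"CAND{i:04d}" for i in range(n_cand)
    ]
    is_candidate = np.zeros(n_genes, dtype=bool)
    is_candidate[n_bg:] = True

    # design: 3 zones x landraces x blocks
    sample_ids, samples = [], []
    landrace_names = []
    idx = 1
    for zone in ZONES:
        for _ in range(config.landraces_per_zone):
            landrace_names.append((f"LR{idx:02d}", zone))
            idx += 1
    for lr, zone in landrace_names:
        for b in range(1, config.n_blocks + 1):
            sample_ids.append(f"{lr}_B{b}")
            samples.append(SampleInfo(lr, zone, b))
    n_samples = len(sample_ids)
    zones = np.array([s.zone for s in samples])
    blocks = np.array([s.block for s in samples])

    # baseline means: candidates from a lower-mean log-normal
    log_mu = rng_mu.normal(config.mean_log_mu, config.sd_log_mu, size=n_genes)
    log_mu[is_candidate] = rng_mu.normal(
        config.candidate_mean_log_mu, config.sd_log_mu, size=n_cand
    )
    mu = np.exp(log_mu)

    # planted DE: per-gene zone-effect vector (delta_midland, delta_highland)
    p_de = np.where(
        is_candidate,
        min(1.0, config.enrichment_factor * config.de_fraction),
        config.de_fraction,
    )
    de_gene = rng_de.random(n_genes) < p_de
    n_de = int(de_gene.sum())
    lfc = np.zeros(n_genes)
    lfc[de_gene] = _truncated_normal_lfc(
        rng_de, n_de, config.log2fc_sd, config.min_abs_log2fc
    )
    pattern = rng_de.choice(
        3,
        size=n_genes,
        p=[config.p_highland_only, config.p_shared, config.p_midland_only],
    )
    delta_h = np.where(de_gene & (pattern != 2), lfc, 0.0)
    delta_m = np.where(de_gene & (pattern != 0), lfc, 0.0)

    # per-gene block effects (log2)
    block_eff = rng_block.normal(
        0.0, config.block_sd, size=(n_genes, config.n_blocks)
    )

    # library depths, centered to geometric mean 1
    sf = np.exp(rng_sf.normal(0.0, config.size_factor_sd, size=n_samples))
    sf = sf / np.exp(np.mean(np.log(sf)))

    zone_shift = np.zeros((n_genes, n_samples))
    zone_shift[:, zones == "midland"] = delta_m[:, None]
    zone_shift[:, zones == "highland"] = delta_h[:, None]
    block_shift = block_eff[:, blocks - 1]
    mean = sf[None, :] * mu[:, None] * 2.0 ** (zone_shift + block_shift)
    counts = _nb_sample(rng_counts, mean, config.dispersion).astype(np.int64)

    cm = CountMatrix(gene_ids, sample_ids, counts, samples)

    min_eff = config.min_abs_log2fc
    truth = pd.DataFrame(
        {
            "is_candidate": is_candidate,
            "baseline_mu": mu,
            "lfc_highland_lowland": delta_h,
            "lfc_highland_midland": delta_h - delta_m,
            "lfc_midland_lowland": delta_m,
            "de_highland_lowland": np.abs(delta_h) >= min_eff,
            "de_highland_midland": np.abs(delta_h - delta_m) >= min_eff,
            "de_midland_lowland": np.abs(delta_m) >= min_eff,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth.attrs["size_factors"] = sf
    truth.attrs["enrichment_factor"] = config.enrichment_factor

    return SyntheticBundle(
        counts=cm,
        candidates=GeneSet("candidates", set(gene_ids[n_bg:])),
        background=GeneSet("background", set(gene_ids[:n_bg])),
        truth=truth,
    )


def paper_like_fixture(seed: int = 0) -> SyntheticBundle:
    """Small preset sized so the full pipeline runs in well under 2 minutes.

    2,000 background genes, 190 candidates, enrichment factor 4, strong
    planted effects (minimum |log2fc| = 1).  Most differential genes are
    shared between highland and midland, so highland and midland libraries
    are transcriptionally closer to each other than either is to lowland —
    the cluster topology the real study observed.
    """
    config = SimConfig(
        n_background_genes=2000,
        n_candidate_genes=190,
        de_fraction=0.15,
        min_abs_log2fc=1.0,
        enrichment_factor=4.0,
        dispersion=0.1,
        p_highland_only=0.25,
        p_shared=0.6,
        p_midland_only=0.15,
        seed=seed,
    )
    return simulate(config)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write counts.tsv, metadata.tsv, candidates.txt, background.txt, truth.tsv."""
    from pathlib import Path

    from . import io as eio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_counts(bundle.counts, out / "counts.tsv")
    eio.write_metadata(
        bundle.counts.sample_ids, bundle.counts.samples, out / "metadata.tsv"
    )
    eio.write_gene_list(bundle.candidates, out / "candidates.txt")
    eio.write_gene_list(bundle.background, out / "background.txt")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t")


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
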