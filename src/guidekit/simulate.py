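"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: genomes of
controlled GC content, pooled knockout screens with a planted
sequence-feature -> efficiency structure and an essential/non-essential gene
mix, editing-outcome allele tables with planted indel-length distributions
and a positional SNV hotspot, and GUIDE-seq-style off-target observation
tables with mismatch-dependent cleavage decay. Each generator is a pure
function of its config and seed; truth sidecars are always available.

Defaults mirror the study conditions the pipeline targets: a mini-human-like
screen (2,061 guides over 687 genes, reference + 4 weekly timepoints,
~15% essential genes so the Bayes-Factor filter leaves roughly 306 guides)
and a high-throughput outcome table (1.91 deletions per insertion, SNVs at
63.4% of variant reads, a ~3x SNV hotspot at protospacer position 17 of the
39-nt window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import BASES
from .features import SNV_WINDOW_LENGTH
from .genome import Genome

PROTOSPACER_OFFSET_IN_WINDOW = 10  # 39-nt window = 10 + 20 + 9
# protospacer position 17 (1-based) in window coordinates (0-based)
DEFAULT_HOTSPOT = PROTOSPACER_OFFSET_IN_WINDOW + 17 - 1


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_dna(n: int, rng, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_rng(rng).choice(list(BASES), size=n, p=p))


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    length: int = 100_000
    gc: float = 0.5
    id: str = "synthetic"


def generate_genome(config: GenomeConfig, seed) -> Genome:
    """i.i.d. bases with P(G)=P(C)=gc/2; empirical GC ~ config.gc."""
    if not 0.0 <= config.gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if config.length < 100:
        raise ValueError("length must be >= 100")
    rng = _rng(seed)
    return Genome(id=config.id, sequence=random_dna(config.length, rng, config.gc))


def genome_gc_panel(
    gc_values, length: int = 20_000, seed: int = 0
) -> list[Genome]:
    """A panel of equal-length genomes sweeping GC content (one seed stream)."""
    rng = _rng(seed)
    return [
        Genome(id=f"gc{gc:.2f}", sequence=random_dna(length, rng, gc))
        for gc in gc_values
    ]


# ---------------------------------------------------------------------------
# pooled knockout screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenConfig:
    n_guides: int = 2061
    n_genes: int = 687
    essential_fraction: float = 0.15
    depth: float = 500.0  # mean reference reads per guide
    timepoints: int = 4  # weekly post-reference timepoints
    # planted per-base weights applied to protospacer global nucleotide counts
    weights: dict = field(
        default_factory=lambda: {"A": -0.15, "C": 0.10, "G": 0.20, "T": -0.10}
    )
    logistic_scale: float = 0.5
    depletion_rate: float = 1.0  # k in 2^(-t * efficiency/100 * k)
    noise_sd: float = 0.1  # lognormal overdispersion of expected counts


def _planted_efficiency(protospacers: list[str], cfg: ScreenConfig) -> np.ndarray:
    """Logistic link from protospacer base composition to efficiency in [0,100]."""
    counts = np.array(
        [[p.count(b) for b in BASES] for p in protospacers], dtype=float
    )
    w = np.array([cfg.weights[b] for b in BASES])
    z = (counts - counts.mean(axis=0)) @ w
    return 100.0 / (1.0 + np.exp(-z / cfg.logistic_scale))


def generate_screen(config: ScreenConfig, seed) -> dict:
    """Pooled screen with planted sequence->efficiency structure.

    Returns {'counts': guide x timepoint table (with gene and 34-nt context),
    'bf': per-gene Bayes-Factor table, 'truth': guide -> planted efficiency}.
    Essential-gene guides deplete as reference * 2^(-t * eff/100 * k); guides
    of non-essential genes stay flat. Counts are Poisson around a lognormal
    overdispersed expectation. Essential genes draw BF above the conventional
    threshold of 6, non-essential genes below.
    """
    if config.n_guides < config.n_genes:
        raise ValueError("n_guides must be >= n_genes")
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = _rng(seed)
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    n_essential = int(round(config.essential_fraction * config.n_genes))
    essential = set(genes[:n_essential])
    bf = pd.DataFrame(
        {
            "gene": genes,
            "bf": [
                6.0 + rng.gamma(2.0, 5.0) if g in essential else rng.normal(-3.0, 3.0)
                for g in genes
            ],
        }
    )
    # assign each guide a gene (every gene gets at least one)
    gene_of_guide = list(genes)
    gene_of_guide += list(rng.choice(genes, size=config.n_guides - config.n_genes))
    rng.shuffle(gene_of_guide)

    # 34-nt context: 4 flank + TTTN + 20 protospacer + 6 flank
    contexts, protos = [], []
    for _ in range(config.n_guides):
        flank5 = random_dna(4, rng)
        pam = "TTT" + random_dna(1, rng)
        proto = random_dna(20, rng)
        flank3 = random_dna(6, rng)
        contexts.append(flank5 + pam + proto + flank3)
        protos.append(proto)
    efficiency = _planted_efficiency(protos, config)

    rows = []
    ref_expect = config.depth * rng.lognormal(0.0, config.noise_sd, config.n_guides)
    for i in range(config.n_guides):
        gene = gene_of_guide[i]
        row = {
            "guide_id": f"guide{i:05d}",
            "gene": gene,
            "contig": "chrS",
            "start": 100 * i,
            "end": 100 * i + 24,
            "strand": "+",
            "context": contexts[i],
            "count_ref": rng.poisson(ref_expect[i]),
        }
        for t in range(1, config.timepoints + 1):
            expect = ref_expect[i]
            if gene in essential:
                expect = expect * 2.0 ** (
                    -t * efficiency[i] / 100.0 * config.depletion_rate
                )
            row[f"count_w{t}"] = rng.poisson(expect)
        rows.append(row)
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "guide_id": counts["guide_id"],
            "gene": counts["gene"],
            "essential": [g in essential for g in counts["gene"]],
            "planted_efficiency": efficiency,
        }
    )
    return {"counts": counts, "bf": bf, "truth": truth}


# ---------------------------------------------------------------------------
# editing outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeConfig:
    n_targets: int = 55
    reads_per_target: int = 2000
    edited_fraction: float = 0.41  # share of reads carrying any variant
    del_ins_ratio: float = 1.91
    snv_share: float = 0.634  # SNV share of variant reads
    del_length_p: float = 0.38  # geometric length parameter
    ins_length_p: float = 0.5
    max_del_length: int | None = None  # set to 5 to emulate the truncation artifact
    window_length: int = SNV_WINDOW_LENGTH
    hotspot_position: int = DEFAULT_HOTSPOT
    hotspot_enrichment: float = 3.0
    outcome_rule_offset: int | None = None  # plant outcome = complement of base here


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def generate_outcomes(config: OutcomeConfig, seed) -> dict:
    """Allele table with planted indel/SNV structure.

    Per read the variant type is drawn from {WT, deletion, insertion, SNV}
    with shares set by edited_fraction, snv_share and del_ins_ratio. Indel
    lengths are geometric (deletions optionally capped); SNV positions are
    multinomial with `hotspot_enrichment`-fold weight at `hotspot_position`;
    SNV outcome bases are uniform over the three non-reference bases unless
    `outcome_rule_offset` plants outcome = complement of the window base at
    that offset. Returns {'alleles': table, 'targets': per-target reference
    windows, 'config': the config}.
    """
    if config.reads_per_target < 1:
        raise ValueError("reads_per_target must be >= 1")
    s = config.snv_share
    if not 0.0 <= s <= 1.0 or not 0.0 <= config.edited_fraction <= 1.0:
        raise ValueError("shares must be in [0, 1]")
    rng = _rng(seed)
    r = config.del_ins_ratio
    p_del = (1 - s) * r / (1 + r)
    p_ins = (1 - s) / (1 + r)
    type_p = np.array([p_del, p_ins, s]) * config.edited_fraction
    probs = np.concatenate([[1 - config.edited_fraction], type_p])
    W = config.window_length
    snv_w = np.ones(W)
    snv_w[config.hotspot_position] = config.hotspot_enrichment
    snv_w /= snv_w.sum()

    allele_rows: dict[tuple, int] = {}
    target_rows = []
    for t in range(config.n_targets):
        target_id = f"target{t:04d}"
        window = random_dna(W, rng)
        target_rows.append({"target_id": target_id, "window": window})
        kinds = rng.choice(4, size=config.reads_per_target, p=probs)
        n_wt = int(np.sum(kinds == 0))
        if n_wt:
            key = (target_id, "WT", 0, 0, None)
            allele_rows[key] = allele_rows.get(key, 0) + n_wt
        for code, vtype in ((1, "deletion"), (2, "insertion"), (3, "SNV")):
            n = int(np.sum(kinds == code))
            for _ in range(n):
                if vtype == "SNV":
                    pos = int(rng.choice(W, p=snv_w))
                    ref = window[pos]
                    if config.outcome_rule_offset is not None:
                        # deterministic rule so the planted signal is learnable
                        out = _COMP[window[config.outcome_rule_offset]]
                        if out == ref:
                            out = BASES[(BASES.index(out) + 1) % 4]
                    else:
                        out = rng.choice([b for b in BASES if b != ref])
                    key = (target_id, "SNV", 1, pos, str(out))
                else:
                    p_len = (
                        config.del_length_p if vtype == "deletion" else config.ins_length_p
                    )
                    length = int(rng.geometric(p_len))
                    if vtype == "deletion" and config.max_del_length is not None:
                        length = min(length, config.max_del_length)
                    lo, hi = min(15, W - 1), min(35, W)
                    if hi <= lo:
                        lo, hi = 0, W
                    pos = int(rng.integers(lo, hi))
                    key = (target_id, vtype, length, pos, None)
                allele_rows[key] = allele_rows.get(key, 0) + 1
    alleles = pd.DataFrame(
        [
            {
                "target_id": k[0],
                "variant_type": k[1],
                "length": k[2],
                "position": k[3],
                "outcome_base": k[4],
                "read_count": v,
            }
            for k, v in allele_rows.items()
        ]
    ).sort_values(["target_id", "variant_type", "length", "position"]).reset_index(
        drop=True
    )
    return {
        "alleles": alleles,
        "targets": pd.DataFrame(target_rows),
        "config": config,
    }


# ---------------------------------------------------------------------------
# GUIDE-seq observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideseqConfig:
    n_guides: int = 18
    on_target_reads: int = 10_000
    decay: float = 0.5  # expected reads scale as decay^mm for cleaved sites
    # sequence-predicted off-target sites per guide at mm 0..5
    predicted_per_mm: tuple = (1, 4, 10, 25, 60, 150)
    # probability a predicted site is cleaved at all, at mm 0..5
    cleave_prob: tuple = (1.0, 0.8, 0.55, 0.3, 0.15, 0.05)
    poisson_reads: bool = True  # False: reads = round(expected), noise-free


def generate_guideseq(config: GuideseqConfig, seed) -> dict:
    """GUIDE-seq-style observation table plus the predicted-site universe.

    Expected reads for a cleaved site at mismatch level m are
    on_target_reads * decay^m; a predicted site is cleaved with probability
    cleave_prob[m]. Returns {'observations', 'predicted'} tables.
    """
    if not 0.0 < config.decay <= 1.0:
        raise ValueError("decay must be in (0, 1]")
    rng = _rng(seed)
    obs_rows, pred_rows = [], []
    for g in range(config.n_guides):
        guide_id = f"gseq{g:03d}"
        for mm, (n_sites, p_cleave) in enumerate(
            zip(config.predicted_per_mm, config.cleave_prob)
        ):
            for s in range(n_sites):
                site_id = f"{guide_id}_mm{mm}_s{s}"
                pred_rows.append(
                    {"guide_id": guide_id, "site_id": site_id, "mismatches": mm}
                )
                on_target = mm == 0 and s == 0
                if on_target:
                    reads = config.on_target_reads
                elif rng.random() < p_cleave:
                    expected = config.on_target_reads * config.decay**mm
                    reads = (
                        int(rng.poisson(expected))
                        if config.poisson_reads
                        else int(round(expected))
                    )
                else:
                    reads = 0
                if reads > 0 or on_target:
                    obs_rows.append(
                        {
                            "guide_id": guide_id,
                            "site_id": site_id,
                            "mismatches": mm,
                            "read_count": reads,
                            "is_on_target": on_target,
                        }
                    )
    return {
        "observations": pd.DataFrame(obs_rows),
        "predicted": pd.DataFrame(pred_rows),
    }


def predicted_counts_per_mm(predicted: pd.DataFrame) -> dict[int, int]:
    """Collapse a predicted-site table to {mismatch level: number of sites}."""
    return predicted.groupby("mismatches")["site_id"].nunique().to_dict()
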