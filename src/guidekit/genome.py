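"""Genome scanning: PAM-constrained guide enumeration and mismatch-tolerant
off-target counting for Cas9 (NGG, 3' PAM) and Cas12a (TTTN, 5' PAM).

Coordinates are 0-based half-open (BED convention) and span protospacer+PAM.
Protospacers are reported 5'->3' on the PAM-carrying strand. Windows containing
a genomic N are skipped; IUPAC N in a PAM pattern matches A/C/G/T only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from ._util import BASES, acgt_run_mask, iupac_match_positions, revcomp, seq_to_codes

PROTOSPACER_LENGTH = 20


@dataclass(frozen=True)
class EnzymeSpec:
    """PAM geometry of a CRISPR effector."""

    name: str
    pam: str
    pam_side: str  # 'three_prime' or 'five_prime' of the protospacer
    protospacer_length: int = PROTOSPACER_LENGTH

    @property
    def site_length(self) -> int:
        return self.protospacer_length + len(self.pam)


CAS9 = EnzymeSpec(name="Cas9", pam="NGG", pam_side="three_prime")
CAS12A = EnzymeSpec(name="Cas12a", pam="TTTN", pam_side="five_prime")

ENZYMES = {"cas9": CAS9, "cas12a": CAS12A}


@dataclass
class Genome:
    """A single contig with lazily computed GC content (over non-N bases)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        seq = self.sequence
        acgt = sum(seq.count(b) for b in BASES)
        if acgt == 0:
            return 0.0
        return (seq.count("G") + seq.count("C")) / acgt


@dataclass(frozen=True)
class GuideSite:
    genome_id: str
    contig: str
    start: int  # 0-based, inclusive; spans protospacer+PAM
    end: int  # exclusive
    strand: str  # '+' or '-'
    protospacer: str  # 20 nt, 5'->3' on the PAM-carrying strand
    pam: str
    context: str | None = None

    @property
    def guide_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


@dataclass
class OffTargetCount:
    guide: GuideSite
    counts: dict[int, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a (possibly gzipped) multi-record FASTA into Genome objects."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    return [Genome(id=rec.id, sequence=str(rec.seq)) for rec in records]


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def _scan_plus(seq: str, enzyme: EnzymeSpec):
    """Yield (start, end, protospacer, pam) for PAM matches on the given strand's
    sequence, coordinates local to that sequence."""
    codes = seq_to_codes(seq)
    plen = enzyme.protospacer_length
    pamlen = len(enzyme.pam)
    site = plen + pamlen
    if codes.size < site:
        return
    pam_hits = iupac_match_positions(codes, enzyme.pam)
    clean = acgt_run_mask(codes, plen)
    for p in pam_hits:
        if enzyme.pam_side == "three_prime":
            proto_start = p - plen
            if proto_start < 0:
                continue
        else:
            proto_start = p + pamlen
            if proto_start + plen > codes.size:
                continue
        if not clean[proto_start]:
            continue
        start = int(min(proto_start, p))
        yield start, start + site, seq[proto_start : proto_start + plen], seq[int(p) : int(p) + pamlen]


def find_guides(genome: Genome, enzyme: EnzymeSpec) -> list[GuideSite]:
    """Enumerate every PAM-valid target site on both strands.

    Sites are sorted by ascending start coordinate, '+' before '-' at ties.
    Overlapping and nested sites are all reported.
    """
    seq = genome.sequence
    n = len(seq)
    sites: list[GuideSite] = []
    for start, end, proto, pam in _scan_plus(seq, enzyme):
        sites.append(
            GuideSite(genome.id, genome.id, start, end, "+", proto, pam)
        )
    rc = revcomp(seq)
    for start, end, proto, pam in _scan_plus(rc, enzyme):
        # map interval on the reverse complement back to forward coordinates
        sites.append(
            GuideSite(genome.id, genome.id, n - end, n - start, "-", proto, pam)
        )
    sites.sort(key=lambda s: (s.start, s.strand, s.end))
    return sites


def _hamming_counts(
    protospacers: list[str], guide_proto: str, max_mm: int
) -> dict[int, int]:
    counts = {m: 0 for m in range(max_mm + 1)}
    if not protospacers:
        return counts
    mat = np.array([seq_to_codes(p) for p in protospacers])
    ref = seq_to_codes(guide_proto)
    mm = (mat != ref).sum(axis=1)
    values, freqs = np.unique(mm, return_counts=True)
    for v, f in zip(values, freqs):
        if v <= max_mm:
            counts[int(v)] = int(f)
    return counts


def count_offtargets(
    guide: GuideSite, genome: Genome, max_mm: int = 5
) -> OffTargetCount:
    """Count genomic sites at each exact mismatch level 0..max_mm.

    A candidate site must carry an exact (IUPAC) PAM match for the enzyme
    implied by the guide's PAM geometry; mismatches are counted over the
    20-nt protospacer only. Sites containing genomic N are excluded.
    """
    if len(guide.protospacer) != PROTOSPACER_LENGTH:
        raise ValueError(
            f"invalid guide: protospacer length {len(guide.protospacer)} != 20"
        )
    if not 0 <= max_mm <= PROTOSPACER_LENGTH:
        raise ValueError("max_mm must be in [0, 20]")
    enzyme = _enzyme_for_guide(guide)
    protos = [s.protospacer for s in find_guides(genome, enzyme)]
    return OffTargetCount(guide=guide, counts=_hamming_counts(protos, guide.protospacer, max_mm))


def _enzyme_for_guide(guide: GuideSite) -> EnzymeSpec:
    for enz in (CAS9, CAS12A):
        if len(guide.pam) == len(enz.pam) and _pam_matches(guide.pam, enz.pam):
            return enz
    raise ValueError(f"cannot infer enzyme from PAM {guide.pam!r}")


def _pam_matches(pam: str, pattern: str) -> bool:
    from ._util import IUPAC

    return len(pam) == len(pattern) and all(
        b in IUPAC[s] for b, s in zip(pam.upper(), pattern.upper())
    )


def target_density(genome: Genome, enzyme: EnzymeSpec) -> float:
    """Guides per bp: |guides| / genome length."""
    if genome.length == 0:
        raise ValueError("zero-length genome")
    return len(find_guides(genome, enzyme)) / genome.length


def cas9_to_cas12a_ratio(genome: Genome) -> float:
    """Ratio of Cas9 to Cas12a target densities; NaN when Cas12a has none."""
    d9 = target_density(genome, CAS9)
    d12 = target_density(genome, CAS12A)
    if d12 == 0:
        return float("nan")
    return d9 / d12


def _safe_kruskal(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    return stats.kruskal(*groups)


def per_guide_offtarget_ratios(
    counts_df: pd.DataFrame, genome_lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-guide Cas9:Cas12a off-target ratios, size-normalised.

    `counts_df` is tidy: columns genome_id, enzyme ('Cas9'/'Cas12a'), guide_id,
    mm, count. Each Cas9 guide's normalised count at a mismatch level is
    divided by the median normalised Cas12a count for that genome and level.
    Returns columns genome_id, mm, ratio.
    """
    df = counts_df.copy()
    df["norm"] = df.apply(
        lambda r: r["count"] / genome_lengths[r["genome_id"]], axis=1
    )
    rows = []
    for (gid, mm), sub in df.groupby(["genome_id", "mm"]):
        cas12 = sub.loc[sub["enzyme"] == "Cas12a", "norm"]
        cas9 = sub.loc[sub["enzyme"] == "Cas9", "norm"]
        if cas12.empty or cas9.empty:
            continue
        denom = float(cas12.median())
        if denom == 0:
            continue
        for v in cas9:
            rows.append({"genome_id": gid, "mm": int(mm), "ratio": v / denom})
    return pd.DataFrame(rows, columns=["genome_id", "mm", "ratio"])


def offtarget_ratio_table(ratio_df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-guide ratios per genome, then compare mismatch levels.

    Input: tidy frame with columns genome_id, mm, ratio. Per genome and level
    the median of per-guide ratios is taken; those per-genome medians form the
    groups. Output rows per mm level: median_ratio, iqr_lo/iqr_hi (25th/75th
    percentiles), n_genomes, and a pairwise rank test (Kruskal-Wallis) against
    the mm=0 level with Bonferroni correction (p multiplied by the number of
    pairwise comparisons, capped at 1). The overall k-sample Kruskal-Wallis
    statistic/p is stored in `DataFrame.attrs['kruskal']`.
    """
    per_genome = (
        ratio_df.groupby(["genome_id", "mm"])["ratio"].median().reset_index()
    )
    levels = sorted(per_genome["mm"].unique())
    groups = {
        mm: per_genome.loc[per_genome["mm"] == mm, "ratio"].to_numpy()
        for mm in levels
    }
    rows = []
    n_comparisons = max(len(levels) - 1, 1)
    base = groups[levels[0]] if levels else np.array([])
    for mm in levels:
        vals = groups[mm]
        med = float(np.median(vals))
        lo, hi = np.percentile(vals, [25, 75])
        p_raw = np.nan
        p_bonf = np.nan
        if mm != levels[0] and len(vals) >= 2 and len(base) >= 2:
            _, p_raw = _safe_kruskal([base, vals])
            p_bonf = min(p_raw * n_comparisons, 1.0)
        rows.append(
            {
                "mm": mm,
                "median_ratio": med,
                "iqr_lo": float(lo),
                "iqr_hi": float(hi),
                "n_genomes": len(vals),
                "p_raw": p_raw,
                "p_bonferroni": p_bonf,
            }
        )
    out = pd.DataFrame(rows)
    if len(levels) >= 2 and all(len(groups[mm]) >= 2 for mm in levels):
        h, p = _safe_kruskal([groups[mm] for mm in levels])
        out.attrs["kruskal"] = {"H": float(h), "p": float(p)}
    else:
        out.attrs["kruskal"] = None
    return out


def sites_to_frame(sites: Iterable[GuideSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": s.genome_id,
                "contig": s.contig,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "protospacer": s.protospacer,
                "pam": s.pam,
            }
            for s in sites
        ],
        columns=["genome_id", "contig", "start", "end", "strand", "protospacer", "pam"],
    )


def frame_to_sites(df: pd.DataFrame) -> list[GuideSite]:
    return [
        GuideSite(
            genome_id=row.genome_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            protospacer=row.protospacer,
            pam=row.pam,
        )
        for row in df.itertuples()
    ]
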