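"""Synthetic data generation for the degraded-hair shotgun pipeline.

Every input the analysis stages consume can be generated here: SNP panels
with population allele frequencies, diploid genotype pairs under the four
relationship classes, sparse error-prone per-site observations, sexed
per-chromosome read-count tables, and short circular-mtDNA fragment sets
with optional terminal deamination damage.

The generators emulate the data regime of century-old rootless hair
shafts sequenced by shotgun NGS: panels of ~1.3 million autosomal SNPs,
samples covering only 1-3% of sites with correlated coverage between
samples, observation error between 0 and 2%, halved X-chromosome read
dosage in males, and mtDNA fragments averaging roughly 40-95 bp, some of
which span the circular origin.

All randomness flows from an explicit integer seed; repeated calls with
the same seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .notation import Diff, parse_diffs

RELATIONSHIPS = ("same_individual", "parent_child", "full_siblings", "unrelated")

#: GRCh37 (hg19) chromosome lengths in bp, autosomes 1-22 plus X.
GRCH37_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
    "X": 155_270_560,
}

AUTOSOMES = tuple(str(i) for i in range(1, 23))

_BASES = np.array(list("ACGT"))

# ---------------------------------------------------------------------------
# SNP panel


@dataclasses.dataclass(frozen=True)
class SNPPanel:
    """A biallelic SNP panel with population alternate-allele frequencies.

    ``sites`` has columns ``site_id, chrom, pos, ref, alt, alt_freq`` with
    1-based positions; ``(chrom, pos)`` pairs are unique, ``ref != alt``
    and ``alt_freq`` lies in [0, 1].
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["site_id", "chrom", "pos", "ref", "alt", "alt_freq"]
        missing = [c for c in required if c not in self.sites.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        f = self.sites["alt_freq"].to_numpy(float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("alt_freq must lie in [0, 1]")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        if self.sites.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("(chrom, pos) pairs must be unique")
        if self.sites["site_id"].duplicated().any():
            raise ValueError("site_id values must be unique")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> np.ndarray:
        return self.sites["site_id"].to_numpy()

    @property
    def freqs(self) -> np.ndarray:
        return self.sites["alt_freq"].to_numpy(float)

    def index_of(self, site_ids: Sequence[str]) -> np.ndarray:
        """Row indices of ``site_ids`` in panel order."""
        lookup = pd.Index(self.sites["site_id"])
        idx = lookup.get_indexer(site_ids)
        if np.any(idx < 0):
            raise KeyError("site_ids not present in panel")
        return idx

    def freqs_for(self, site_ids: Sequence[str]) -> np.ndarray:
        return self.freqs[self.index_of(site_ids)]

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df)


def _draw_freqs(freq_law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` alternate-allele frequencies from a pluggable law.

    ``freq_law`` is either a callable ``(rng, n) -> array`` or a tuple:
    ``("uniform", lo, hi)``, ``("constant", v)`` or ``("beta", a, b)``.
    """
    if callable(freq_law):
        return np.asarray(freq_law(rng, n), dtype=float)
    kind = freq_law[0]
    if kind == "uniform":
        return rng.uniform(freq_law[1], freq_law[2], size=n)
    if kind == "constant":
        return np.full(n, float(freq_law[1]))
    if kind == "beta":
        return rng.beta(freq_law[1], freq_law[2], size=n)
    raise ValueError(f"unknown frequency law: {freq_law!r}")


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Sample ``n`` distinct 1-based positions uniformly from ``1..length``."""
    if n > length:
        raise ValueError("more sites requested than positions available")
    draws = rng.integers(1, length + 1, size=int(n * 1.02) + 16)
    pool = np.unique(draws)
    while pool.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pool = np.union1d(pool, extra)
    keep = rng.permutation(pool.size)[:n]
    return np.sort(pool[keep])


def simulate_panel(
    n_sites: int,
    freq_law=("uniform", 0.05, 0.95),
    seed: int | None = None,
    freq_floor: float = 1e-3,
) -> SNPPanel:
    """Simulate an autosomal SNP panel with i.i.d. population frequencies.

    Sites are spread across autosomes 1-22 proportionally to GRCh37
    chromosome lengths. The default frequency law, uniform(0.05, 0.95),
    stands in for common-variant European allele frequencies; any
    alternative law can be plugged in. ``freq_floor`` bounds frequencies
    away from 0 and 1 so that no site is exactly monomorphic.
    """
    n_sites = int(n_sites)
    if n_sites < 1:
        raise ValueError("n_sites must be a positive integer")
    rng = np.random.default_rng(seed)
    freqs = np.clip(_draw_freqs(freq_law, n_sites, rng), freq_floor, 1.0 - freq_floor)

    lengths = np.array([GRCH37_CHROM_LENGTHS[c] for c in AUTOSOMES], dtype=float)
    chrom_idx = rng.choice(len(AUTOSOMES), size=n_sites, p=lengths / lengths.sum())

    chroms = np.empty(n_sites, dtype=object)
    positions = np.empty(n_sites, dtype=np.int64)
    for ci, chrom in enumerate(AUTOSOMES):
        mask = chrom_idx == ci
        k = int(mask.sum())
        if k:
            chroms[mask] = chrom
            positions[mask] = _unique_positions(rng, k, GRCH37_CHROM_LENGTHS[chrom])

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    order = np.lexsort((positions, chrom_idx))
    df = pd.DataFrame(
        {
            "site_id": [f"s{i:08d}" for i in range(n_sites)],
            "chrom": chroms[order],
            "pos": positions[order],
            "ref": _BASES[ref_idx[order]],
            "alt": _BASES[alt_idx[order]],
            "alt_freq": freqs[order],
        }
    )
    return SNPPanel(df)


# ---------------------------------------------------------------------------
# Genotype pairs under the four relationship classes


@dataclasses.dataclass(frozen=True)
class GenotypePair:
    """Diploid genotypes of two individuals on a shared panel.

    Genotype arrays have shape ``(n_sites, 2)`` with entries 0 (ref
    allele) or 1 (alt allele), in panel site order.
    """

    relationship: str
    site_ids: np.ndarray
    genotypes_a: np.ndarray
    genotypes_b: np.ndarray


def _sample_genotype_pairs(
    freqs: np.ndarray, relationship: str, n_pairs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised genotype-pair sampler: returns two (n_pairs, S, 2) arrays.

    Founders are drawn under Hardy-Weinberg equilibrium from the panel
    frequencies. ``parent_child`` transmits one random parental allele to
    the child and pairs it with a fresh population draw; ``full_siblings``
    are two children of the same two simulated parents; ``same_individual``
    duplicates one founder; ``unrelated`` draws two independent founders.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship: {relationship!r}")
    shape = (n_pairs, freqs.size)

    def allele() -> np.ndarray:
        return rng.random(shape) < freqs

    def pick(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.where(rng.random(shape) < 0.5, x, y)

    if relationship == "same_individual":
        g = np.stack([allele(), allele()], axis=-1)
        return g, g.copy()
    if relationship == "unrelated":
        return (
            np.stack([allele(), allele()], axis=-1),
            np.stack([allele(), allele()], axis=-1),
        )
    if relationship == "parent_child":
        p1, p2 = allele(), allele()
        transmitted = pick(p1, p2)
        child = np.stack([transmitted, allele()], axis=-1)
        return np.stack([p1, p2], axis=-1), child
    # full_siblings
    m1, m2 = allele(), allele()
    f1, f2 = allele(), allele()
    sib_a = np.stack([pick(m1, m2), pick(f1, f2)], axis=-1)
    sib_b = np.stack([pick(m1, m2), pick(f1, f2)], axis=-1)
    return sib_a, sib_b


def simulate_genotype_pair(
    panel: SNPPanel, relationship: str, seed: int | None = None
) -> GenotypePair:
    """Simulate one diploid genotype pair on ``panel`` under ``relationship``."""
    rng = np.random.default_rng(seed)
    ga, gb = _sample_genotype_pairs(panel.freqs, relationship, 1, rng)
    return GenotypePair(
        relationship=relationship,
        site_ids=panel.site_ids,
        genotypes_a=ga[0].astype(np.int8),
        genotypes_b=gb[0].astype(np.int8),
    )


def sample_pseudohaploid_pairs(
    freqs: np.ndarray,
    relationship: str,
    n_pairs: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw pseudo-haploid allele pairs (one random allele per individual).

    Returns two boolean arrays of shape ``(n_pairs, n_sites)`` indicating
    the alternate allele. This is the sampling primitive behind the
    mismatch-proportion null distributions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ga, gb = _sample_genotype_pairs(np.asarray(freqs, float), relationship, n_pairs, rng)
    shape = ga.shape[:2]
    hap_a = np.where(rng.random(shape) < 0.5, ga[..., 0], ga[..., 1])
    hap_b = np.where(rng.random(shape) < 0.5, gb[..., 0], gb[..., 1])
    return hap_a, hap_b


# ---------------------------------------------------------------------------
# Coverage masks with correlated coverage


@dataclasses.dataclass(frozen=True)
class CoverageMask:
    """Covered site sets of two sparsely sequenced samples."""

    covered_a: np.ndarray
    covered_b: np.ndarray
    overlap_correlation: float

    @property
    def overlap(self) -> np.ndarray:
        """Site ids covered in both samples."""
        return np.intersect1d(self.covered_a, self.covered_b)


def simulate_coverage_mask(
    panel: SNPPanel,
    n_covered_a: int,
    n_covered_b: int,
    overlap_correlation: float = 0.0,
    seed: int | None = None,
) -> CoverageMask:
    """Sample which panel sites each of two samples covers.

    Coverage correlation is modelled with a latent per-site mappability
    weight shared by both samples: weights are lognormal with log-scale
    ``sigma = 2 * overlap_correlation`` and each sample takes a weighted
    sample without replacement (Gumbel top-k, i.e. successive sampling).
    At ``overlap_correlation = 0`` the weights are uniform and the overlap
    count follows the hypergeometric law; larger values concentrate both
    samples on the same high-weight sites, inflating the expected overlap
    monotonically. This reproduces the empirical observation that two
    libraries from the same tissue share ~3x more covered SNPs than
    independent sampling would predict (at ``overlap_correlation ~ 0.5``).
    """
    n = panel.n_sites
    if not (0 <= n_covered_a <= n and 0 <= n_covered_b <= n):
        raise ValueError("requested coverage exceeds panel size")
    if not 0.0 <= overlap_correlation <= 1.0:
        raise ValueError("overlap_correlation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if overlap_correlation > 0:
        log_w = rng.normal(0.0, 2.0 * overlap_correlation, size=n)
    else:
        log_w = np.zeros(n)
    ids = panel.site_ids

    def take(k: int) -> np.ndarray:
        keys = log_w + rng.gumbel(size=n)
        idx = np.argpartition(-keys, k - 1)[:k] if k else np.empty(0, dtype=int)
        return np.sort(ids[idx])

    return CoverageMask(
        covered_a=take(int(n_covered_a)),
        covered_b=take(int(n_covered_b)),
        overlap_correlation=float(overlap_correlation),
    )


# ---------------------------------------------------------------------------
# Observation error and observation tables


def apply_observation_error(
    alleles,
    error_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Flip each observed allele to the other panel allele with prob ``error_rate``.

    The error model is a symmetric biallelic flip applied independently to
    every observation; it lumps together deamination, depurination, PCR,
    sequencing and mapping error. ``error_rate`` must lie in [0, 0.5): at
    0.5 and beyond the observation carries no information about the true
    allele and the model is undefined.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.asarray(alleles)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).astype(np.int8)
    flips = rng.random(arr.shape) < error_rate
    out = arr ^ flips.astype(np.int8)
    return out[0] if scalar else out


def sample_observations(
    pair: GenotypePair,
    panel: SNPPanel,
    mask: CoverageMask,
    error_rate: float = 0.0,
    reads_per_site: int = 1,
    sample_ids: tuple[str, str] = ("A", "B"),
    seed: int | None = None,
) -> pd.DataFrame:
    """Turn genotypes + coverage into an observed-allele table.

    Each covered site yields ``reads_per_site`` observations; every
    observation samples one of the individual's two alleles uniformly and
    is then flipped with probability ``error_rate``. Returns a long table
    with columns ``sample_id, site_id, allele`` where ``allele`` is the
    observed base.
    """
    rng = np.random.default_rng(seed)
    ref = panel.sites["ref"].to_numpy()
    alt = panel.sites["alt"].to_numpy()
    frames = []
    for label, genotypes, covered in (
        (sample_ids[0], pair.genotypes_a, mask.covered_a),
        (sample_ids[1], pair.genotypes_b, mask.covered_b),
    ):
        idx = panel.index_of(covered)
        g = genotypes[idx]
        for _ in range(int(reads_per_site)):
            drawn = np.where(rng.random(idx.size) < 0.5, g[:, 0], g[:, 1])
            drawn = apply_observation_error(drawn, error_rate, rng=rng)
            bases = np.where(drawn == 1, alt[idx], ref[idx])
            frames.append(
                pd.DataFrame(
                    {"sample_id": label, "site_id": covered, "allele": bases}
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_observations_tsv(observations: pd.DataFrame, path) -> None:
    observations.to_csv(path, sep="\t", index=False)


def read_observations_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Per-chromosome read counts for sexing


def simulate_chromosome_counts(
    sex: str,
    total_reads: int,
    chrom_lengths: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multinomial per-chromosome read counts for a female or male sample.

    Reads land on chromosomes with probability proportional to
    ``length * dosage`` where the X-chromosome dosage is 1 for females
    (XX) and 0.5 for males (XY); autosomes always have dosage 1. Returns
    a table with columns ``chrom, n_reads, length_bp`` for chr1-22 and X.
    Y-chromosome reads are not modelled; the Rx statistic ignores them.
    """
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    if total_reads < 0:
        raise ValueError("total_reads must be non-negative")
    if chrom_lengths is None:
        chrom_lengths = GRCH37_CHROM_LENGTHS
    chroms = list(AUTOSOMES) + ["X"]
    missing = [c for c in chroms if c not in chrom_lengths]
    if missing:
        raise ValueError(f"missing chromosome lengths: {missing}")
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    dosage = np.ones(len(chroms))
    dosage[-1] = 1.0 if sex == "female" else 0.5
    weights = lengths * dosage
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(total_reads), weights / weights.sum())
    return pd.DataFrame(
        {"chrom": chroms, "n_reads": counts, "length_bp": lengths.astype(np.int64)}
    )


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# Circular mtDNA read simulation


@dataclasses.dataclass(frozen=True)
class MtRead:
    """One sequenced mtDNA fragment in circular-reference coordinates.

    ``start_rcrs`` is the 1-based reference position of the first aligned
    base; ``length`` is the reference footprint (number of non-inserted
    bases); ``sequence`` additionally contains any inserted bases, each
    annotated in ``insertions`` as ``(anchor_position, rank, base)``.
    Sequences are stored reference-oriented regardless of strand.
    """

    read_id: str
    start_rcrs: int
    length: int
    sequence: str
    is_origin_spanning: bool
    strand: str = "+"
    mapping_quality: int = 60
    insertions: tuple[tuple[int, int, str], ...] = ()


@dataclasses.dataclass(frozen=True)
class MtReadSet:
    reads: tuple[MtRead, ...]
    source_haplotype: tuple[str, ...]
    deamination_rate: float
    reference_length: int


def random_mt_reference(length: int = 16_569, seed: int | None = None, gc: float = 0.44) -> str:
    """A synthetic circular mtDNA-like reference sequence.

    This is a random sequence with human-mtDNA-like length and GC content,
    a synthetic stand-in for an rCRS-like genome; it is not the rCRS.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=int(length), p=p)])


def lognormal_length_law(
    mean: float, sd: float | None = None, min_len: int = 20
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Fragment-length law: lognormal with the given mean, floored at ``min_len``.

    Degraded-hair mtDNA fragments average roughly 40-95 bp depending on
    sample and library; a right-skewed lognormal with sd defaulting to
    0.35 * mean matches that regime.
    """
    if sd is None:
        sd = 0.35 * mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2

    def law(rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.lognormal(mu, np.sqrt(sigma2), size=n)
        return np.maximum(min_len, np.rint(draws).astype(np.int64))

    return law


def _mutated_circle(reference: str, diffs: Sequence[Diff]):
    """Apply substitutions/insertions to a circular reference.

    Returns ``(mut_seq, anchors, ranks)`` where position ``i`` of the
    mutated sequence carries reference anchor ``anchors[i]`` and insertion
    rank ``ranks[i]`` (0 for non-inserted bases).
    """
    L = len(reference)
    subs: dict[int, str] = {}
    ins: dict[int, list[tuple[int, str]]] = {}
    for d in diffs:
        if not 1 <= d.pos <= L:
            raise ValueError(f"haplotype difference outside 1..{L}: {d}")
        if d.base not in "ACGT":
            raise ValueError(
                f"only A/C/G/T haplotype differences can be simulated: {d}"
            )
        if d.rank == 0:
            subs[d.pos] = d.base
        else:
            ins.setdefault(d.pos, []).append((d.rank, d.base))
    for pos in ins:
        ins[pos].sort()
        ranks = [r for r, _ in ins[pos]]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"insertion ranks at {pos} must be 1..k: {ranks}")

    seq_parts: list[str] = []
    anchors: list[int] = []
    ranks_out: list[int] = []
    for pos in range(1, L + 1):
        seq_parts.append(subs.get(pos, reference[pos - 1]))
        anchors.append(pos)
        ranks_out.append(0)
        for rank, base in ins.get(pos, ()):
            seq_parts.append(base)
            anchors.append(pos)
            ranks_out.append(rank)
    return "".join(seq_parts), np.array(anchors), np.array(ranks_out)


def simulate_mt_reads(
    reference: str,
    haplotype_diffs: Iterable[str] = (),
    depth_target: float = 60.0,
    length_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    mean_length: float = 65.0,
    deamination_rate: float = 0.0,
    mapping_quality: int = 60,
    seed: int | None = None,
) -> MtReadSet:
    """Simulate shotgun reads from a mutated circular mtDNA genome.

    The source haplotype (``haplotype_diffs``, forensic difference
    notation) is applied to the circular reference; fragments start
    uniformly on the circle, lengths follow ``length_law`` (default:
    lognormal with ``mean_length``), and reads are emitted until the mean
    per-position depth reaches ``depth_target``. Fragments whose
    reference footprint crosses the origin (position L -> 1) are flagged
    origin-spanning. With probability ``deamination_rate`` each terminal
    base of a fragment that is a C is rendered as T, mimicking hydrolytic
    deamination damage concentrated at fragment ends.
    """
    if depth_target <= 0:
        raise ValueError("depth_target must be positive")
    if not 0.0 <= deamination_rate <= 1.0:
        raise ValueError("deamination_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    diffs = parse_diffs(haplotype_diffs)
    L = len(reference)
    mut, anchors, ranks = _mutated_circle(reference, diffs)
    Lm = len(mut)
    if length_law is None:
        length_law = lognormal_length_law(mean_length)

    target_bases = depth_target * L
    covered = 0
    reads: list[MtRead] = []
    batch: list[int] = []

    def next_length() -> int:
        nonlocal batch
        if not batch:
            batch = list(length_law(rng, 256))
        return int(batch.pop())

    i = 0
    while covered < target_bases:
        s = int(rng.integers(Lm))
        while ranks[s] != 0:  # start reads on a non-inserted base
            s = (s + 1) % Lm
        ln = min(next_length(), Lm)
        if s + ln <= Lm:
            seq = mut[s : s + ln]
            span_ranks = ranks[s : s + ln]
            span_anchors = anchors[s : s + ln]
        else:
            seq = mut[s:] + mut[: s + ln - Lm]
            span_ranks = np.concatenate([ranks[s:], ranks[: s + ln - Lm]])
            span_anchors = np.concatenate([anchors[s:], anchors[: s + ln - Lm]])
        footprint = int((span_ranks == 0).sum())
        insertions = tuple(
            (int(a), int(r), seq[j])
            for j, (a, r) in enumerate(zip(span_anchors, span_ranks))
            if r != 0
        )
        if deamination_rate > 0:
            chars = list(seq)
            for end in (0, len(chars) - 1):
                if chars[end] == "C" and rng.random() < deamination_rate:
                    chars[end] = "T"
            seq = "".join(chars)
            insertions = tuple(
                (a, r, seq[j])
                for (a, r, _), j in zip(
                    insertions,
                    [k for k, r in enumerate(span_ranks) if r != 0],
                )
            )
        start_rcrs = int(anchors[s])
        reads.append(
            MtRead(
                read_id=f"mt{i:06d}",
                start_rcrs=start_rcrs,
                length=footprint,
                sequence=seq,
                is_origin_spanning=start_rcrs + footprint - 1 > L,
                strand="+" if rng.random() < 0.5 else "-",
                mapping_quality=int(mapping_quality),
                insertions=insertions,
            )
        )
        covered += footprint
        i += 1
    return MtReadSet(
        reads=tuple(reads),
        source_haplotype=tuple(str(d) for d in sorted(diffs)),
        deamination_rate=float(deamination_rate),
        reference_length=L,
    )


def write_mt_fasta(readset: MtReadSet, path) -> None:
    """Write simulated read sequences as FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        for r in readset.reads
    ]
    SeqIO.write(records, path, "fasta")


def write_mt_placements_tsv(readset: MtReadSet, path) -> None:
    """Write the circular-coordinate placement table for simulated reads."""
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in readset.reads],
            "start_rcrs": [r.start_rcrs for r in readset.reads],
            "length": [r.length for r in readset.reads],
            "origin_spanning": [int(r.is_origin_spanning) for r in readset.reads],
            "strand": [r.strand for r in readset.reads],
            "mapping_quality": [r.mapping_quality for r in readset.reads],
            "insertions": [
                ";".join(f"{a}.{k}{b}" for a, k, b in r.insertions)
                for r in readset.reads
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
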