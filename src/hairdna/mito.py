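"""Circular mitochondrial genome handling: chimeric reference, liftover,
deduplication, filtering, pileup consensus with point-heteroplasmy calls,
and haplotype difference lists.

Linear short-read aligners cannot place fragments that span the origin of
a circular genome. The standard workaround is a chimeric linearised
reference: the full genome, a spacer of Ns, then a second copy of the
genome rotated to start mid-sequence, so that every circular fragment has
a contiguous linear home in one of the two copies. For an rCRS-length
genome (16,569 bp) with the canonical rotation point 8284 and a 14 N
spacer, the chimera is 33,152 bp long. Placements on the chimera are
lifted back to circular (rCRS) coordinates by arithmetic, duplicates and
low mapping quality reads are removed, and a per-position pileup yields
consensus calls, with two-base mixtures (point heteroplasmies) rendered
as IUPAC codes and insertions in ``anchor.rank`` notation.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .notation import IUPAC_TWO, Diff, parse_diff, sort_key

_BASE_COLS = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_COL_BASES = "ACGT-"


class PlacementRejected(ValueError):
    """A placement cannot be lifted to circular coordinates (e.g. it
    overlaps the N spacer of the chimeric reference)."""


# ---------------------------------------------------------------------------
# Chimeric reference


@dataclasses.dataclass(frozen=True)
class ChimericReference:
    """Doubled-and-rotated linearisation of a circular genome.

    Layout (1-based): positions ``1..L`` are the genome as-is, positions
    ``L+1..L+spacer_len`` are Ns, and positions ``L+spacer_len+1..2L+spacer_len``
    are the genome rotated to start at ``rotation_origin``.
    """

    sequence: str
    ref_length: int
    rotation_origin: int
    spacer_len: int

    @property
    def spacer_start(self) -> int:
        return self.ref_length + 1

    @property
    def spacer_end(self) -> int:
        return self.ref_length + self.spacer_len

    @property
    def copy2_origin(self) -> int:
        return self.rotation_origin

    def to_fasta(self, path, name: str = "chrM_chimeric") -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        SeqIO.write([SeqRecord(Seq(self.sequence), id=name, description="")], path, "fasta")


def build_chimeric_reference(
    reference: str, rotation_origin: int = 8284, spacer_len: int = 14
) -> ChimericReference:
    """Build the chimeric linear reference for a circular genome.

    The second copy starts at ``rotation_origin`` and, being a full
    rotation, ends at ``rotation_origin - 1``. For a 16,569 bp genome
    with the defaults the result is 2*16569 + 14 = 33,152 bp.
    """
    reference = str(reference)
    L = len(reference)
    if not 1 <= rotation_origin <= L:
        raise ValueError(f"rotation_origin must lie in 1..{L}")
    if spacer_len < 0:
        raise ValueError("spacer_len must be non-negative")
    seq = (
        reference
        + "N" * spacer_len
        + reference[rotation_origin - 1 :]
        + reference[: rotation_origin - 1]
    )
    return ChimericReference(
        sequence=seq,
        ref_length=L,
        rotation_origin=int(rotation_origin),
        spacer_len=int(spacer_len),
    )


# ---------------------------------------------------------------------------
# Placements and liftover


@dataclasses.dataclass(frozen=True)
class MtPlacement:
    """A read placed on the chimeric reference.

    ``length`` is the reference footprint in bp. ``sequence`` holds the
    read bases in reference orientation and may include inserted bases,
    each annotated in ``insertions`` as ``(anchor, rank, base)`` with the
    anchor in chimeric coordinates; liftover converts anchors to circular
    coordinates.
    """

    read_id: str
    chimeric_start: int
    length: int
    mapping_quality: int
    sequence: str = ""
    strand: str = "+"
    insertions: tuple[tuple[int, int, str], ...] = ()


@dataclasses.dataclass(frozen=True)
class LiftedPlacement:
    """A placement expressed in circular (rCRS) coordinates.

    ``intervals`` holds one inclusive 1-based interval, or two for
    origin-spanning reads (e.g. ``((16565, 16569), (1, 5))``).
    """

    read_id: str
    start_rcrs: int
    length: int
    mapping_quality: int
    intervals: tuple[tuple[int, int], ...]
    sequence: str = ""
    strand: str = "+"
    insertions: tuple[tuple[int, int, str], ...] = ()

    @property
    def end_rcrs(self) -> int:
        return self.intervals[-1][1]

    @property
    def is_origin_spanning(self) -> bool:
        return len(self.intervals) == 2


def rcrs_position(chimeric_pos: int, chim: ChimericReference) -> int:
    """Map one chimeric position to its circular (rCRS) coordinate."""
    L, sp = chim.ref_length, chim.spacer_len
    if not 1 <= chimeric_pos <= 2 * L + sp:
        raise PlacementRejected(f"chimeric position {chimeric_pos} out of bounds")
    if chimeric_pos <= L:
        return chimeric_pos
    if chimeric_pos <= L + sp:
        raise PlacementRejected(f"chimeric position {chimeric_pos} lies in the N spacer")
    return (chimeric_pos - (L + sp) + chim.rotation_origin - 2) % L + 1


def liftover_to_rcrs(placement: MtPlacement, chim: ChimericReference) -> LiftedPlacement:
    """Lift a chimeric placement back to circular coordinates.

    Placements on the first copy map identically; placements on the
    rotated second copy are shifted by the rotation, and footprints that
    cross the circular origin split into two intervals. Placements that
    overlap the N spacer (or run off the chimera) are rejected.
    """
    L, sp = chim.ref_length, chim.spacer_len
    start, end = placement.chimeric_start, placement.chimeric_start + placement.length - 1
    if placement.length < 1:
        raise PlacementRejected("placement length must be >= 1")
    if start < 1 or end > 2 * L + sp:
        raise PlacementRejected("placement extends beyond the chimeric reference")
    if start <= chim.spacer_end and end >= chim.spacer_start:
        raise PlacementRejected("placement overlaps the N spacer")
    start_rcrs = rcrs_position(start, chim)
    last = start_rcrs + placement.length - 1
    if last <= L:
        intervals = ((start_rcrs, last),)
    else:
        intervals = ((start_rcrs, L), (1, last - L))
    lifted_ins = tuple(
        (rcrs_position(a, chim), r, b) for a, r, b in placement.insertions
    )
    return LiftedPlacement(
        read_id=placement.read_id,
        start_rcrs=start_rcrs,
        length=placement.length,
        mapping_quality=placement.mapping_quality,
        intervals=intervals,
        sequence=placement.sequence,
        strand=placement.strand,
        insertions=lifted_ins,
    )


def lift_placements(
    placements: Iterable[MtPlacement], chim: ChimericReference
) -> tuple[list[LiftedPlacement], list[tuple[MtPlacement, str]]]:
    """Lift many placements; returns (lifted, rejected-with-reason)."""
    lifted: list[LiftedPlacement] = []
    rejected: list[tuple[MtPlacement, str]] = []
    for pl in placements:
        try:
            lifted.append(liftover_to_rcrs(pl, chim))
        except PlacementRejected as exc:
            rejected.append((pl, str(exc)))
    return lifted, rejected


def filter_placements(placements: Iterable, min_mq: int = 30) -> list:
    """Retain placements with mapping quality >= ``min_mq`` (default 30)."""
    return [pl for pl in placements if pl.mapping_quality >= min_mq]


def deduplicate(placements: Iterable[LiftedPlacement]) -> list[LiftedPlacement]:
    """Collapse presumed PCR duplicates.

    Placements sharing identical circular fragment endpoints and strand
    collapse to a single representative: the highest mapping quality,
    ties broken by smallest read_id. Idempotent; input order of distinct
    fragments is preserved.
    """
    best: dict[tuple, LiftedPlacement] = {}
    order: list[tuple] = []
    for pl in placements:
        key = (pl.intervals, pl.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = pl
            order.append(key)
        elif (-pl.mapping_quality, pl.read_id) < (-cur.mapping_quality, cur.read_id):
            best[key] = pl
    return [best[k] for k in order]


def process_placements(
    placements: Sequence[MtPlacement],
    chim: ChimericReference,
    min_mq: int = 30,
) -> tuple[list[LiftedPlacement], dict[str, int]]:
    """Liftover -> mapping-quality filter -> deduplicate.

    Returns the retained placements plus an accounting dict satisfying
    ``n_input == n_spacer_rejected + n_mq_filtered + n_duplicates_removed
    + n_retained``.
    """
    lifted, rejected = lift_placements(placements, chim)
    hq = filter_placements(lifted, min_mq=min_mq)
    unique = deduplicate(hq)
    counts = {
        "n_input": len(placements),
        "n_spacer_rejected": len(rejected),
        "n_mq_filtered": len(lifted) - len(hq),
        "n_duplicates_removed": len(hq) - len(unique),
        "n_retained": len(unique),
    }
    return unique, counts


# ---------------------------------------------------------------------------
# Pileup and consensus calling


@dataclasses.dataclass(frozen=True)
class InsertionCall:
    anchor: int
    rank: int
    base: str
    support: int
    anchor_depth: int

    def __str__(self) -> str:
        return f"{self.anchor}.{self.rank}{self.base}"


@dataclasses.dataclass
class MtCallSet:
    """Per-position base counts and consensus calls on a circular genome.

    ``counts`` has shape ``(L, 5)`` with columns A, C, G, T, deletion;
    ``consensus[i]`` is a single base, an IUPAC two-base code for a point
    heteroplasmy, ``-`` for a deletion, or ``""`` for a no-call (zero
    depth). ``major_fraction[i]`` is the majority-base share of depth.
    """

    ref_length: int
    counts: np.ndarray
    consensus: np.ndarray
    heteroplasmic: np.ndarray
    major_fraction: np.ndarray
    insertions: tuple[InsertionCall, ...]
    het_min_fraction: float
    het_min_reads: int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def called_positions(self) -> np.ndarray:
        """1-based positions with nonzero depth."""
        return np.nonzero(self.depth > 0)[0] + 1


def call_base_counts(
    counts: Mapping[str, int],
    het_min_fraction: float = 0.10,
    het_min_reads: int = 2,
) -> tuple[str, float, bool]:
    """Consensus call from base counts at one position.

    Returns ``(call, major_fraction, is_heteroplasmic)``. The call is the
    majority base unless the minor base reaches both ``het_min_fraction``
    of the depth and ``het_min_reads`` reads, in which case the position
    is a point heteroplasmy and the call is the IUPAC code of the two
    bases. ``major_fraction`` is majority count / total depth (e.g.
    57 T + 18 C -> call Y, major fraction 0.76). Zero depth returns
    ``("", nan, False)``: absence of data is a no-call, never a
    reference match.
    """
    items = [(b, int(c)) for b, c in counts.items() if c > 0 and b in _BASE_COLS]
    depth = sum(c for _, c in items)
    if depth == 0:
        return "", float("nan"), False
    items.sort(key=lambda bc: (-bc[1], bc[0]))
    major, major_n = items[0]
    frac = major_n / depth
    if len(items) > 1:
        minor, minor_n = items[1]
        if minor_n >= het_min_reads and minor_n / depth >= het_min_fraction:
            pair = frozenset((major, minor))
            if "-" in pair:
                # mixed deletion: report the non-deleted majority state
                return major, frac, True
            return IUPAC_TWO[pair], frac, True
    return major, frac, False


def _walk_read(pl: LiftedPlacement, L: int):
    """Yield per-base assignments of a read: matched positions and insertions.

    Returns ``(positions, bases, insertion_obs)`` where ``positions`` are
    the 1-based footprint coordinates in read order, ``bases`` the
    corresponding sequence characters, and ``insertion_obs`` the observed
    ``(anchor, rank, base)`` triples. Insertions must be anchored at a
    footprint position of the read.
    """
    ins_by_anchor: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for a, r, b in sorted(pl.insertions, key=lambda t: (t[0], t[1])):
        ins_by_anchor[a].append((r, b))
    positions: list[int] = []
    bases: list[str] = []
    ins_obs: list[tuple[int, int, str]] = []
    i = 0
    pos = pl.start_rcrs
    seq = pl.sequence
    for _ in range(pl.length):
        positions.append(pos)
        bases.append(seq[i])
        i += 1
        for rank, _base in ins_by_anchor.get(pos, ()):
            ins_obs.append((pos, rank, seq[i]))
            i += 1
        pos = pos % L + 1
    return positions, bases, ins_obs


def pileup_and_call(
    placements: Sequence[LiftedPlacement],
    reference: str,
    het_min_fraction: float = 0.10,
    het_min_reads: int = 2,
) -> MtCallSet:
    """Pile up lifted, deduplicated placements and call a consensus.

    Substitution consensus and heteroplasmy logic follow
    :func:`call_base_counts`. An insertion ``anchor.rank`` is called when
    it is supported by at least ``het_min_reads`` reads and by at least
    half of the reads covering its anchor position.
    """
    L = len(reference)
    counts = np.zeros((L, 5), dtype=np.int64)

    simple_pos: list[np.ndarray] = []
    simple_seq: list[str] = []
    ins_support: Counter = Counter()
    for pl in placements:
        if not pl.insertions:
            if len(pl.sequence) != pl.length:
                raise ValueError(
                    f"read {pl.read_id}: sequence length does not match footprint"
                )
            simple_pos.append((pl.start_rcrs - 1 + np.arange(pl.length)) % L)
            simple_seq.append(pl.sequence)
        else:
            positions, bases, ins_obs = _walk_read(pl, L)
            for p, b in zip(positions, bases):
                col = _BASE_COLS.get(b)
                if col is not None:
                    counts[p - 1, col] += 1
            for obs in ins_obs:
                ins_support[obs] += 1
    if simple_pos:
        flat_pos = np.concatenate(simple_pos)
        flat = np.frombuffer("".join(simple_seq).encode("ascii"), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int8)
        for b, c in _BASE_COLS.items():
            lut[ord(b)] = c
        cols = lut[flat]
        ok = cols >= 0
        np.add.at(counts, (flat_pos[ok], cols[ok]), 1)

    depth = counts.sum(axis=1)
    consensus = np.full(L, "", dtype="<U1")
    het = np.zeros(L, dtype=bool)
    major_fraction = np.full(L, np.nan)
    for i in np.nonzero(depth > 0)[0]:
        row = {b: int(counts[i, c]) for b, c in _BASE_COLS.items() if counts[i, c]}
        call, frac, is_het = call_base_counts(row, het_min_fraction, het_min_reads)
        consensus[i] = call
        het[i] = is_het
        major_fraction[i] = frac

    ins_calls: list[InsertionCall] = []
    for (anchor, rank, base), support in sorted(ins_support.items()):
        anchor_depth = int(depth[anchor - 1])
        if support >= het_min_reads and support >= 0.5 * anchor_depth:
            ins_calls.append(InsertionCall(anchor, rank, base, support, anchor_depth))

    return MtCallSet(
        ref_length=L,
        counts=counts,
        consensus=consensus,
        heteroplasmic=het,
        major_fraction=major_fraction,
        insertions=tuple(ins_calls),
        het_min_fraction=het_min_fraction,
        het_min_reads=het_min_reads,
    )


# ---------------------------------------------------------------------------
# Haplotype difference lists


def haplotype_diff(callset: MtCallSet, reference: str) -> list[str]:
    """Express a consensus as an ordered difference list vs the reference.

    Substitutions render as ``positionBase`` (IUPAC code for mixed
    positions), insertions as ``anchor.rankBase``. No-call positions
    contribute nothing.
    """
    L = len(reference)
    if L != callset.ref_length:
        raise ValueError("reference length does not match call set")
    diffs: list[Diff] = []
    for i in np.nonzero(callset.depth > 0)[0]:
        call = str(callset.consensus[i])
        if call and call != reference[i]:
            diffs.append(Diff(i + 1, 0, call))
    for ins in callset.insertions:
        diffs.append(Diff(ins.anchor, ins.rank, ins.base))
    return [str(d) for d in sorted(diffs, key=sort_key)]


@dataclasses.dataclass(frozen=True)
class HaplotypeComparison:
    shared: tuple[str, ...]
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]

    @property
    def n_differences(self) -> int:
        return len(self.only_a) + len(self.only_b)


def compare_haplotypes(
    diffs_a: Iterable[str],
    diffs_b: Iterable[str],
    called_a: Iterable[int] | None = None,
    called_b: Iterable[int] | None = None,
) -> HaplotypeComparison:
    """Shared and private differences between two haplotype diff lists.

    When per-sample called-position sets are supplied, the comparison is
    restricted to positions called in both samples, so that missing data
    in one profile is never counted as a difference.
    """
    a = {parse_diff(d) for d in diffs_a}
    b = {parse_diff(d) for d in diffs_b}
    if called_a is not None and called_b is not None:
        both = set(called_a) & set(called_b)
        a = {d for d in a if d.pos in both}
        b = {d for d in b if d.pos in both}
    return HaplotypeComparison(
        shared=tuple(str(d) for d in sorted(a & b, key=sort_key)),
        only_a=tuple(str(d) for d in sorted(a - b, key=sort_key)),
        only_b=tuple(str(d) for d in sorted(b - a, key=sort_key)),
    )


# ---------------------------------------------------------------------------
# Depth and fragment-length statistics


@dataclasses.dataclass(frozen=True)
class DepthLengthStats:
    depth_mean: float
    depth_min: int
    depth_max: int
    depth_sd: float
    mean_length: float
    length_hist: dict[int, int]

    @property
    def n_reads(self) -> int:
        return sum(self.length_hist.values())


def depth_length_stats(
    callset: MtCallSet, placements: Sequence[LiftedPlacement]
) -> DepthLengthStats:
    """Depth summaries over all reference positions and the fragment-length
    distribution (1 bp bins) of the unique placements."""
    if not placements:
        raise ValueError("no placements: depth/length statistics undefined")
    depth = callset.depth
    lengths = np.array([len(pl.sequence) or pl.length for pl in placements])
    hist = np.bincount(lengths)
    return DepthLengthStats(
        depth_mean=float(depth.mean()),
        depth_min=int(depth.min()),
        depth_max=int(depth.max()),
        depth_sd=float(depth.std(ddof=1)) if depth.size > 1 else 0.0,
        mean_length=float(lengths.mean()),
        length_hist={int(l): int(c) for l, c in enumerate(hist) if c},
    )


# ---------------------------------------------------------------------------
# I/O adapters


def place_reads_on_chimera(readset, chim: ChimericReference) -> list[MtPlacement]:
    """Place simulated circular-coordinate reads onto the chimeric reference.

    Non-wrapping reads sit in the first copy at their own coordinate;
    origin-spanning reads are placed contiguously in the rotated second
    copy, exactly as a linear aligner would place them.
    """
    L, sp, origin = chim.ref_length, chim.spacer_len, chim.rotation_origin

    def to_copy2(pos: int) -> int:
        return L + sp + ((pos - origin) % L) + 1

    placements = []
    for r in readset.reads:
        if r.is_origin_spanning:
            start = to_copy2(r.start_rcrs)
            ins = tuple((to_copy2(a), k, b) for a, k, b in r.insertions)
        else:
            start = r.start_rcrs
            ins = r.insertions
        placements.append(
            MtPlacement(
                read_id=r.read_id,
                chimeric_start=start,
                length=r.length,
                mapping_quality=r.mapping_quality,
                sequence=r.sequence,
                strand=r.strand,
                insertions=ins,
            )
        )
    return placements


def placements_to_tsv(placements: Sequence[MtPlacement], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "read_id": [p.read_id for p in placements],
            "chimeric_start": [p.chimeric_start for p in placements],
            "length": [p.length for p in placements],
            "mapping_quality": [p.mapping_quality for p in placements],
            "strand": [p.strand for p in placements],
            "sequence": [p.sequence for p in placements],
            "insertions": [
                ";".join(f"{a}.{k}{b}" for a, k, b in p.insertions)
                for p in placements
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def placements_from_tsv(path) -> list[MtPlacement]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        ins = tuple(
            (d.pos, d.rank, d.base)
            for d in (parse_diff(t) for t in str(row.insertions).split(";") if t)
        )
        out.append(
            MtPlacement(
                read_id=str(row.read_id),
                chimeric_start=int(row.chimeric_start),
                length=int(row.length),
                mapping_quality=int(row.mapping_quality),
                sequence=str(row.sequence),
                strand=str(row.strand),
                insertions=ins,
            )
        )
    return out


def placements_from_sam(path) -> tuple[list[MtPlacement], list[tuple[str, str]]]:
    """Ingest SAM alignments against the chimeric reference.

    Produces the same placement table the simulator emits. CIGAR I
    operations become insertion annotations anchored at the preceding
    reference base (circular coordinates are assigned later, at
    liftover); soft/hard clips are trimmed. Reads with deletions or
    skips, unmapped reads, and secondary/supplementary records are
    skipped with a reason.
    """
    import pysam

    placements: list[MtPlacement] = []
    skipped: list[tuple[str, str]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                skipped.append((aln.query_name, "unmapped"))
                continue
            if aln.is_secondary or aln.is_supplementary:
                skipped.append((aln.query_name, "secondary/supplementary"))
                continue
            cigar = aln.cigartuples or []
            if any(op in (2, 3) for op, _ in cigar):  # D, N
                skipped.append((aln.query_name, "deletion/skip unsupported"))
                continue
            seq = aln.query_sequence or ""
            chim_start = aln.reference_start + 1  # 1-based
            parts: list[str] = []
            ins: list[tuple[int, int, str]] = []
            qi = 0
            ref_off = 0  # footprint bases consumed so far
            for op, n in cigar:
                if op in (0, 7, 8):  # M, =, X
                    parts.append(seq[qi : qi + n])
                    qi += n
                    ref_off += n
                elif op == 1:  # I: anchored at the previous footprint offset
                    if ref_off == 0:
                        skipped.append((aln.query_name, "leading insertion"))
                        parts = []
                        break
                    for k in range(n):
                        ins.append((ref_off, k + 1, seq[qi + k]))
                    parts.append(seq[qi : qi + n])
                    qi += n
                elif op == 4:  # S
                    qi += n
                elif op == 5:  # H
                    pass
                else:
                    skipped.append((aln.query_name, f"unsupported CIGAR op {op}"))
                    parts = []
                    break
            if not parts:
                continue
            # insertion anchors recorded as footprint offsets; convert to
            # chimeric coordinates here (liftover maps them to circular).
            anchored = tuple(
                (chim_start + off - 1, rank, base) for off, rank, base in ins
            )
            placements.append(
                MtPlacement(
                    read_id=aln.query_name,
                    chimeric_start=chim_start,
                    length=ref_off,
                    mapping_quality=aln.mapping_quality,
                    sequence="".join(parts),
                    strand="-" if aln.is_reverse else "+",
                    insertions=anchored,
                )
            )
    return placements, skipped


def write_vcf(callset: MtCallSet, reference: str, path, contig: str = "chrM") -> None:
    """Write substitution/insertion calls as a minimal single-contig VCF."""
    L = len(reference)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={L}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    depth = callset.depth
    for i in np.nonzero(depth > 0)[0]:
        call = str(callset.consensus[i])
        ref_base = reference[i]
        if not call or call == ref_base:
            continue
        if call in "ACGT":
            alts = [call]
            af = [callset.major_fraction[i]]
        elif call == "-":
            continue  # simple-deletion VCF records are out of scope
        else:  # IUPAC heteroplasmy: report the non-reference base(s)
            from .notation import IUPAC_TWO_INV

            bases = sorted(IUPAC_TWO_INV[call])
            alts = [b for b in bases if b != ref_base]
            col = {"A": 0, "C": 1, "G": 2, "T": 3}
            af = [callset.counts[i, col[b]] / depth[i] for b in alts]
        alt_field = ",".join(alts)
        af_field = ",".join(f"{x:.4f}" for x in af)
        lines.append(
            f"{contig}\t{i + 1}\t.\t{ref_base}\t{alt_field}\t.\tPASS\tDP={int(depth[i])};AF={af_field}"
        )
    for ins in callset.insertions:
        ref_base = reference[ins.anchor - 1]
        af = ins.support / ins.anchor_depth if ins.anchor_depth else 0.0
        lines.append(
            f"{contig}\t{ins.anchor}\t.\t{ref_base}\t{ref_base}{ins.base}\t.\tPASS\t"
            f"DP={ins.anchor_depth};AF={af:.4f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
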