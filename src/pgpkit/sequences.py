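"""cDNA and protein characterization.

Assembles overlapping cDNA fragments (the in-silico analog of fusion PCR),
locates the longest open reading frame on either strand, translates it, and
characterizes the deduced protein: average-mass molecular weight, theoretical
isoelectric point (Bjellqvist pKa set, bisection), N-glycosylation sequons
(N-X-S/T, X != P), and pairwise global alignment identity.

Coordinates are 0-based half-open internally; reported residue positions
(e.g. glycosylation sites) are 1-based, the convention of sequence-feature
annotation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# Average (isotope-abundance weighted) residue masses in daltons, i.e. the
# amino-acid mass minus one water; summing residues and adding back one water
# gives the mass of the intact chain.
WATER_MASS = 18.01524
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Bjellqvist ionizable-group pKa values (the set behind the classic ExPASy
# Compute pI tool). Terminal pKs depend on the terminal residue.
BJELLQVIST_PKA = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                         "T": 6.82, "V": 7.44, "E": 7.7},
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD_TABLE.stop_codons)


class SequenceError(ValueError):
    """Contract violation on a sequence operation."""


class AssemblyGapError(SequenceError):
    """Fragments cannot be chained: some junction lacks a sufficient overlap."""


class AssemblyAmbiguityError(SequenceError):
    """More than one distinct assembly is consistent with the overlaps."""


class AmbiguousCodonError(SequenceError):
    """A codon contains an N and permissive translation is off."""


class NoOrfError(SequenceError):
    """No ATG-to-stop frame exists on either strand."""


@dataclass(frozen=True)
class NucSeq:
    """A nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - NUC_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSeq":
        return NucSeq(self.id, str(Seq(self.residues).reverse_complement()),
                      self.description)


@dataclass(frozen=True)
class ProtSeq:
    """A protein sequence in one-letter code, optionally '*'-terminated."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        body = self.residues[:-1] if self.residues.endswith("*") else self.residues
        bad = set(body) - AA_ALPHABET - {"X"}
        if bad:
            raise SequenceError(
                f"protein {self.id!r} contains invalid residues {sorted(bad)}"
            )
        if "*" in body:
            raise SequenceError(f"protein {self.id!r} has an internal stop")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain(self) -> str:
        """Residues without any terminal stop marker."""
        return self.residues.rstrip("*")


@dataclass(frozen=True)
class OrfResult:
    """An open reading frame on a nucleotide sequence.

    ``start``/``end`` are 0-based half-open coordinates on the *input* (+)
    sequence; for strand '-', the reading frame runs on the reverse
    complement of ``seq[start:end]``. The stop codon is included, so
    ``length_nt`` is 3 * (protein length + 1).
    """

    start: int
    end: int
    strand: str
    protein: ProtSeq
    length_nt: int = field(default=0)

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise SequenceError("ORF length not divisible by 3")
        object.__setattr__(self, "length_nt", self.end - self.start)


@dataclass(frozen=True)
class GlycoSite:
    """A potential N-linked glycosylation sequon (N-X-S/T, X != P)."""

    position: int  # 1-based index of the asparagine
    sequon: str

    def __post_init__(self) -> None:
        if not (len(self.sequon) == 3 and self.sequon[0] == "N"
                and self.sequon[1] != "P" and self.sequon[2] in "ST"):
            raise SequenceError(f"{self.sequon!r} is not an N-X-S/T sequon")


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float


# ---------------------------------------------------------------------------
# fragment assembly

def _max_overlap(left: str, right: str, min_overlap: int) -> int:
    """Longest exact suffix(left)/prefix(right) overlap >= min_overlap, else 0."""
    limit = min(len(left), len(right))
    for k in range(limit, min_overlap - 1, -1):
        if left[-k:] == right[:k]:
            return k
    return 0


def assemble_overlapping_fragments(fragments: list[NucSeq],
                                   min_overlap: int) -> NucSeq:
    """Merge fragments sharing exact suffix-prefix overlaps into one sequence.

    Fragment order is inferred from the overlap graph, not from input order.
    Raises :class:`AssemblyGapError` when no single chain covers all
    fragments, and :class:`AssemblyAmbiguityError` when more than one
    distinct assembled sequence is consistent with the overlaps.
    """
    if len(fragments) < 2:
        raise SequenceError("need at least two fragments to assemble")
    if min_overlap < 1:
        raise SequenceError("min_overlap must be positive")

    n = len(fragments)
    overlap = {}
    for i, j in itertools.permutations(range(n), 2):
        k = _max_overlap(fragments[i].residues, fragments[j].residues, min_overlap)
        if k:
            overlap[(i, j)] = k

    def merged(order: tuple[int, ...]) -> str:
        out = fragments[order[0]].residues
        for a, b in zip(order, order[1:]):
            out += fragments[b].residues[overlap[(a, b)]:]
        return out

    chains = [
        order for order in itertools.permutations(range(n))
        if all((a, b) in overlap for a, b in zip(order, order[1:]))
    ]
    if not chains:
        raise AssemblyGapError(
            f"no ordering of the {n} fragments has >= {min_overlap} bp overlap "
            "at every junction"
        )
    sequences = {merged(order) for order in chains}
    if len(sequences) > 1:
        raise AssemblyAmbiguityError(
            f"{len(chains)} fragment orderings yield {len(sequences)} distinct "
            "assemblies"
        )
    seq = sequences.pop()
    ids = "+".join(fragments[i].id for i in chains[0])
    return NucSeq(ids, seq, f"assembly of {n} fragments")


# ---------------------------------------------------------------------------
# translation and ORF finding

def translate(seq: NucSeq, frame: int = 0, *, to_stop: bool = False,
              permissive: bool = False) -> ProtSeq:
    """Translate one forward frame with the standard genetic code.

    Trailing bases that do not fill a codon are ignored. A codon containing
    N raises :class:`AmbiguousCodonError` unless ``permissive``, in which
    case it is rendered as 'X'. With ``to_stop`` translation ends at the
    first stop codon (which is not emitted).
    """
    if frame not in (0, 1, 2):
        raise SequenceError("frame must be 0, 1 or 2")
    out = []
    s = seq.residues
    for i in range(frame, len(s) - 2, 3):
        codon = s[i:i + 3]
        if "N" in codon:
            if not permissive:
                raise AmbiguousCodonError(
                    f"ambiguous codon {codon!r} at position {i}"
                )
            out.append("X")
            continue
        if codon in STOP_CODONS:
            if to_stop:
                break
            out.append("*")
            if i + 3 < len(s) - 2:
                # an internal stop cannot appear in a ProtSeq; report it
                raise SequenceError(
                    f"internal stop codon at position {i} in frame {frame}"
                )
        else:
            out.append(_STANDARD_TABLE.forward_table[codon])
    return ProtSeq(seq.id, "".join(out))


def _orfs_one_strand(s: str):
    """Yield (start, end) of every maximal ATG..stop frame; end excludes nothing
    (stop codon included)."""
    for frame in range(3):
        start = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                yield start, i + 3
                start = None


def find_longest_orf(seq: NucSeq) -> OrfResult:
    """Longest ATG-to-stop reading frame on either strand.

    Ties are broken in favor of the + strand, then the smallest start
    coordinate. The stop codon counts toward the ORF length.
    """
    if len(seq) < 6:
        raise SequenceError("sequence shorter than one codon pair")
    candidates = []  # (length, strand_rank, start_on_input, strand, s, e_local)
    fwd = seq.residues
    rev = seq.reverse_complement().residues
    L = len(fwd)
    for s, e in _orfs_one_strand(fwd):
        candidates.append((e - s, 0, s, "+", s, e))
    for s, e in _orfs_one_strand(rev):
        # map [s, e) on the reverse complement back to input coordinates
        candidates.append((e - s, 1, L - e, "-", L - e, L - s))
    if not candidates:
        raise NoOrfError(f"no open reading frame in {seq.id!r}")
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    _, _, _, strand, start, end = candidates[0]
    coding = fwd[start:end] if strand == "+" else rev[L - end:L - start]
    prot = translate(NucSeq(seq.id, coding), 0, to_stop=True)
    return OrfResult(start=start, end=end, strand=strand, protein=prot)


# ---------------------------------------------------------------------------
# protein characterization

def molecular_weight(prot: ProtSeq) -> float:
    """Average-mass molecular weight of the chain in daltons.

    Sum of standard average residue masses plus one water (18.01524 Da).
    """
    chain = prot.chain
    if not chain:
        raise SequenceError("empty protein")
    try:
        return sum(AVERAGE_RESIDUE_MASS[r] for r in chain) + WATER_MASS
    except KeyError as exc:
        raise SequenceError(f"no mass for residue {exc.args[0]!r}") from exc


def net_charge(prot: ProtSeq, ph: float,
               pka: dict | None = None) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch sum).

    Positive groups (N-terminus, K, R, H) contribute 1/(1+10^(pH-pK));
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pK-pH)).
    """
    chain = prot.chain
    if not chain:
        raise SequenceError("empty protein")
    pka = pka or BJELLQVIST_PKA
    pos_pk = pka["positive"]
    neg_pk = pka["negative"]
    nterm_pk = pka["nterm_by_residue"].get(chain[0], pos_pk["Nterm"])
    cterm_pk = pka["cterm_by_residue"].get(chain[-1], neg_pk["Cterm"])

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(nterm_pk) + neg(cterm_pk)
    for r in chain:
        if r in pos_pk and r != "Nterm":
            charge += pos(pos_pk[r])
        elif r in neg_pk:
            charge += neg(neg_pk[r])
    return charge


def isoelectric_point(prot: ProtSeq, pka: dict | None = None,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(prot, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def scan_nglyc_sequons(prot: ProtSeq) -> list[GlycoSite]:
    """All N-X-S/T sequons (X != P), 1-based asparagine positions.

    Overlapping sequons are each reported.
    """
    chain = prot.chain
    sites = []
    for i in range(len(chain) - 2):
        tri = chain[i:i + 3]
        if tri[0] == "N" and tri[1] != "P" and tri[2] in "ST":
            sites.append(GlycoSite(position=i + 1, sequon=tri))
    return sites


def global_align(a: ProtSeq, b: ProtSeq, *, matrix: str = "BLOSUM62",
                 gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> PairwiseAlignment:
    """Optimal global alignment under a substitution matrix with affine gaps.

    Identity is matched columns over all alignment columns, gaps included.
    """
    if not a.chain or not b.chain:
        raise SequenceError("cannot align an empty protein")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a.chain, b.chain)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y for x, y in zip(sa, sb))
    return PairwiseAlignment(aligned_a=sa, aligned_b=sb,
                             score=float(aln.score),
                             identity=matches / len(sa))


# ---------------------------------------------------------------------------
# FASTA I/O and report

def read_fasta(path) -> list[NucSeq]:
    records = [NucSeq(r.id, str(r.seq).upper(), r.description)
               for r in SeqIO.parse(str(path), "fasta")]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate ids in FASTA input")
    return records


def write_fasta(path, seqs) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id,
                         description=getattr(s, "description", ""))
               for s in seqs]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def characterize_cdna(seq: NucSeq) -> dict:
    """Full characterization of a cDNA: ORF, deduced protein, MW, pI, sequons.

    Returns a plain dict suitable for JSON serialization, with 1-based sequon
    positions.
    """
    orf = find_longest_orf(seq)
    prot = orf.protein
    return {
        "cdna_id": seq.id,
        "cdna_length_nt": len(seq),
        "orf": {"start": orf.start, "end": orf.end, "strand": orf.strand,
                "length_nt": orf.length_nt},
        "protein_length_aa": len(prot.chain),
        "molecular_weight_da": round(molecular_weight(prot), 3),
        "isoelectric_point": round(isoelectric_point(prot), 2),
        "n_glycosylation_sites": [
            {"position": s.position, "sequon": s.sequon}
            for s in scan_nglyc_sequons(prot)
        ],
    }
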