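"""Readers and writers for the standard formats the pipeline touches.

Formats: FASTA alignments, two-column TSV population maps, GenePop genotype
files, Newick dated (ultrametric) trees, and TSV tip->area assignment files.
All readers validate strictly and raise :class:`FormatError` on malformed
input rather than guessing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# Bases that carry unambiguous state information; anything else in
# {IUPAC ambiguity codes, N, -} is treated as missing at that site.
_UNAMBIGUOUS = "ACGT"
_ALLOWED = set("ACGTUNRYSWKMBDHV-?")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Alignment:
    """Fixed-length nucleotide alignment with per-sample identifiers.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per sequence.
    sequences
        Equal-length uppercase nucleotide strings over the IUPAC alphabet
        (plus ``-`` and ``?``).
    locus_label
        Free-text label for the locus (e.g. ``"COI"``).
    """

    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    locus_label: str = ""

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise FormatError("sample_ids and sequences differ in length")
        if len(self.sample_ids) == 0:
            raise FormatError("empty alignment")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"ragged sequence lengths: {sorted(lengths)}")
        if lengths == {0}:
            raise FormatError("zero-length alignment")
        for sid, seq in zip(self.sample_ids, self.sequences):
            bad = set(seq) - _ALLOWED
            if bad:
                raise FormatError(f"invalid characters {sorted(bad)} in sequence {sid!r}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_codes(self) -> np.ndarray:
        """Encode as an (n, length) int8 matrix: A=0 C=1 G=2 T=3, missing=-1."""
        lut = np.full(256, -1, dtype=np.int8)
        for base, code in _CODE.items():
            lut[ord(base)] = code
        raw = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return lut[raw].reshape(self.n, self.length)

    def subset(self, sample_ids) -> "Alignment":
        """Restrict to the given samples, preserving alignment columns."""
        wanted = list(sample_ids)
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return Alignment(
            tuple(wanted),
            tuple(self.sequences[index[s]] for s in wanted),
            self.locus_label,
        )

    def concat(self, other: "Alignment", locus_label: str = "") -> "Alignment":
        """Per-sample concatenation; samples present in only one locus are dropped."""
        shared = [s for s in self.sample_ids if s in set(other.sample_ids)]
        if not shared:
            raise FormatError("no shared samples to concatenate")
        left = self.subset(shared)
        right = other.subset(shared)
        seqs = tuple(a + b for a, b in zip(left.sequences, right.sequences))
        return Alignment(tuple(shared), seqs, locus_label or f"{self.locus_label}+{other.locus_label}")


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of samples to populations, ordered by first appearance."""

    assignments: dict  # sample_id -> population label
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.populations:
            raise FormatError("population map must define at least one population")
        pops = set(self.populations)
        for sid, pop in self.assignments.items():
            if pop not in pops:
                raise FormatError(f"sample {sid!r} mapped to unknown population {pop!r}")

    @classmethod
    def from_pairs(cls, pairs) -> "PopulationMap":
        assignments: dict = {}
        order: list = []
        for sid, pop in pairs:
            if sid in assignments:
                raise FormatError(f"sample {sid!r} listed more than once")
            assignments[sid] = pop
            if pop not in order:
                order.append(pop)
        if not assignments:
            raise FormatError("empty population map")
        return cls(assignments, tuple(order))

    def samples_in(self, pop: str) -> list:
        return [s for s, p in self.assignments.items() if p == pop]

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid allele-size calls per sample x locus.

    ``calls`` has shape (n_samples, n_loci, 2) with allele sizes as positive
    integers and missing alleles encoded as -1.
    """

    sample_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]
    calls: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls)
        if calls.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise FormatError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise FormatError("duplicate locus ids")
        valid = calls[calls >= 0]
        if valid.size and valid.min() <= 0:
            raise FormatError("allele sizes must be positive integers")
        object.__setattr__(self, "calls", calls)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids) -> "GenotypeTable":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeTable(tuple(sample_ids), self.locus_ids, self.calls[rows], self.ploidy)


class DatedTree:
    """Rooted ultrametric tree with branch lengths in time units (e.g. mya).

    Node ages are derived from branch lengths; tips sit at age 0 within
    tolerance ``1e-6 * root_age``.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._assign_ages()

    def _assign_ages(self) -> None:
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                node.depth = 0.0
            else:
                if node.edge.length is None:
                    raise FormatError("tree has a branch with no length")
                node.depth = node.parent_node.depth + node.edge.length
        leaves = [lf for lf in self.tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise FormatError("dated tree needs at least 2 tips")
        max_depth = max(lf.depth for lf in leaves)
        tol = 1e-6 * max_depth if max_depth > 0 else 1e-12
        for lf in leaves:
            if abs(lf.depth - max_depth) > tol:
                raise FormatError(
                    f"tree is not ultrametric: tip {lf.taxon.label!r} at depth "
                    f"{lf.depth:.8g} vs root age {max_depth:.8g}"
                )
        for node in self.tree.preorder_node_iter():
            node.age = max_depth - node.depth
        for lf in leaves:
            lf.age = 0.0
        self.root_age = max_depth

    @property
    def tip_labels(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_alignment(path, expected_length: int | None = None, locus_label: str = "") -> Alignment:
    """Read a FASTA file as an :class:`Alignment`.

    Raises
    ------
    FormatError
        On empty files, ragged sequence lengths, or (when ``expected_length``
        is given) a length mismatch.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    aln = Alignment(ids, seqs, locus_label or os.path.splitext(os.path.basename(str(path)))[0])
    if expected_length is not None and aln.length != expected_length:
        raise FormatError(f"alignment length {aln.length} != expected {expected_length}")
    return aln


def write_fasta_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Population map (TSV)


def read_popmap(path) -> PopulationMap:
    """Read a two-column TSV (sample_id, population); order of first
    appearance fixes the population ordering."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>population'")
            pairs.append((parts[0], parts[1]))
    return PopulationMap.from_pairs(pairs)


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sid, pop in popmap.assignments.items():
            fh.write(f"{sid}\t{pop}\n")


# ---------------------------------------------------------------------------
# GenePop

# Hand-rolled on purpose: the contract requires detection of mixed 2/3-digit
# coding and odd allele-string lengths, which library parsers silently accept.


def read_genepop(path) -> tuple[GenotypeTable, PopulationMap]:
    """Parse a GenePop file (2- or 3-digit allele coding, never mixed).

    Returns the genotype table and the population map implied by ``Pop``
    separator blocks; populations are labelled ``pop1`` .. ``popK`` in file
    order. ``00``/``000`` alleles decode to missing.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated GenePop file")
    # line 0 is the title; locus names follow until the first Pop line
    locus_ids: list = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                locus_ids.append(name)
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: no 'Pop' separator found")
    if not locus_ids:
        raise FormatError(f"{path}: no locus names before first 'Pop'")

    sample_ids: list = []
    pairs: list = []
    rows: list = []
    pop_index = 0
    digits: int | None = None
    anon = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_index += 1
            i += 1
            continue
        line = lines[i]
        if "," in line:
            name, _, geno_part = line.partition(",")
            name = name.strip()
        else:
            name, geno_part = "", line
        if not name:
            anon += 1
            name = f"sample{anon}"
        fields = geno_part.split()
        if len(fields) != len(locus_ids):
            raise FormatError(
                f"{path}: individual {name!r} has {len(fields)} genotypes, expected {len(locus_ids)}"
            )
        row = []
        for locus, tok in zip(locus_ids, fields):
            if len(tok) % 2 != 0 or len(tok) not in (4, 6):
                raise FormatError(
                    f"{path}: allele string {tok!r} at locus {locus} has invalid length"
                )
            width = len(tok) // 2
            if digits is None:
                digits = width
            elif width != digits:
                raise FormatError(
                    f"{path}: mixed {digits}- and {width}-digit allele coding (locus {locus})"
                )
            try:
                a, b = int(tok[:width]), int(tok[width:])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric allele string {tok!r}") from exc
            row.append((a if a > 0 else -1, b if b > 0 else -1))
        if name in set(sample_ids):
            name = f"{name}.{pop_index}"
        sample_ids.append(name)
        pairs.append((name, f"pop{pop_index}"))
        rows.append(row)
        i += 1
    if not rows:
        raise FormatError(f"{path}: no individuals")
    calls = np.array(rows, dtype=np.int32)
    gt = GenotypeTable(tuple(sample_ids), tuple(locus_ids), calls)
    return gt, PopulationMap.from_pairs(pairs)


def write_genepop(gt: GenotypeTable, popmap: PopulationMap, path, title: str = "phylopop export") -> None:
    """Write a 3-digit GenePop file with one ``Pop`` block per population."""
    index = {sid: i for i, sid in enumerate(gt.sample_ids)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gt.locus_ids:
            fh.write(locus + "\n")
        for pop in popmap.populations:
            fh.write("Pop\n")
            for sid in popmap.samples_in(pop):
                row = gt.calls[index[sid]]
                toks = []
                for a, b in row:
                    a = 0 if a < 0 else int(a)
                    b = 0 if b < 0 else int(b)
                    toks.append(f"{a:03d}{b:03d}")
                fh.write(f"{sid} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# Newick dated trees


def read_newick_dated(path_or_string) -> DatedTree:
    """Read a Newick tree with branch lengths and verify ultrametricity."""
    src = str(path_or_string)
    if os.path.exists(src):
        tree = dendropy.Tree.get(path=src, schema="newick")
    else:
        tree = dendropy.Tree.get(data=src, schema="newick")
    return DatedTree(tree)


def write_newick_dated(dt: DatedTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(dt.newick() + "\n")


# ---------------------------------------------------------------------------
# Tip -> area assignments (TSV: tip TAB comma-separated areas)


def read_tip_areas(path) -> dict:
    """Read tip->areas TSV; values are tuples of area labels."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'tip<TAB>area1,area2,...'")
            tip, areas = parts
            if tip in out:
                raise FormatError(f"{path}:{lineno}: duplicate tip {tip!r}")
            out[tip] = tuple(a.strip() for a in areas.split(",") if a.strip())
            if not out[tip]:
                raise FormatError(f"{path}:{lineno}: tip {tip!r} has no areas")
    if not out:
        raise FormatError(f"{path}: empty tip-area file")
    return out


def write_tip_areas(tip_areas: dict, path) -> None:
    with open(path, "w") as fh:
        for tip, areas in tip_areas.items():
            fh.write(f"{tip}\t{','.join(areas)}\n")
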