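"""Sequence and site-annotation I/O, dataset filters, and peptide-window extraction.

A pupylation dataset is a set of proteins, each with zero or more annotated
modified lysines (1-based positions). Candidate sites are all lysines; each is
represented by a fixed-length peptide window centred on the K, padded with
``'-'`` where the window runs past a sequence end. Positives are the annotated
lysines, negatives the rest; the class imbalance is handled by uniform
subsampling of negatives at a configurable ratio (3:1 by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

DEFAULT_FLANK = 10
DEFAULT_MIN_LENGTH = 50
DEFAULT_IDENTITY = 0.40
DEFAULT_NEG_RATIO = 3


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its annotated pupylation lysine positions.

    Parameters
    ----------
    id : str
        Unique identifier.
    sequence : str
        Amino-acid sequence (uppercase).
    sites : tuple of int
        1-based positions of annotated pupylation sites; each must point at
        a ``'K'`` residue.
    """

    id: str
    sequence: str
    sites: tuple[int, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Raise ``ValueError`` if any annotated site is out of range or non-K."""
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for pos in self.sites:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"protein {self.id!r}: site {pos} outside [1, {len(self.sequence)}]"
                )
            if self.sequence[pos - 1] != "K":
                raise ValueError(
                    f"protein {self.id!r}: site {pos} is "
                    f"{self.sequence[pos - 1]!r}, expected 'K'"
                )


@dataclass(frozen=True)
class PeptideWindow:
    """A ``2*flank+1``-residue fragment centred on a candidate lysine.

    ``residues`` uses ``'-'`` for positions beyond the protein's ends; the
    padding is always a contiguous prefix and/or suffix. ``label`` is 1 for an
    annotated (pupylated) centre, 0 otherwise. Window sites are addressed
    1..2*flank+1 left to right, the centre at flank+1 (site 11 at the default
    flank of 10).
    """

    protein_id: str
    center: int
    residues: str
    label: int

    @property
    def flank(self) -> int:
        return (len(self.residues) - 1) // 2


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects (no sites attached).

    Sequences are uppercased and input order is preserved. Raises
    ``ValueError`` on a file whose first non-blank line is not a header, or on
    duplicate identifiers.
    """
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}: line {lineno} is not FASTA (expected '>'): {line!r}")
        break
    records = []
    seen = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        path,
        "fasta",
    )


def read_sites(path) -> dict[str, list[int]]:
    """Read a TSV of ``protein_id<TAB>position`` rows into a per-protein site map.

    A header line ``protein_id\\tposition`` is accepted and skipped. Positions
    are deduplicated and returned ascending. Non-integer positions raise.
    """
    sites: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            pid, pos_s = parts
            if lineno == 1 and pid == "protein_id" and pos_s == "position":
                continue
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            sites.setdefault(pid, set()).add(pos)
    return {pid: sorted(ps) for pid, ps in sites.items()}


def write_sites(site_map: dict[str, list[int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\n")
        for pid in site_map:
            for pos in site_map[pid]:
                fh.write(f"{pid}\t{pos}\n")


def attach_sites(records, site_map) -> list[ProteinRecord]:
    """Merge a site map onto records; validates that every site hits a 'K'."""
    out = []
    for rec in records:
        merged = replace(rec, sites=tuple(site_map.get(rec.id, ())))
        merged.validate()
        out.append(merged)
    return out


def filter_proteins(records, min_length: int = DEFAULT_MIN_LENGTH) -> list[ProteinRecord]:
    """Drop fragments (< ``min_length`` residues) and sequences with letters
    outside the 20 standard amino acids; order preserved."""
    return [
        r
        for r in records
        if len(r.sequence) >= min_length and set(r.sequence) <= _STANDARD_SET
    ]


def _make_aligner() -> PairwiseAligner:
    # Global alignment with free end gaps; identity = matches / columns.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    try:  # Biopython >= 1.86 naming
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def sequence_identity(a: str, b: str) -> float:
    """Pairwise identity between two sequences.

    Defined as exact matches divided by alignment columns under a global,
    end-gap-free alignment (match 1, mismatch 0, gap open −5, extend −1).
    """
    aln = _ALIGNER.align(a, b)[0]
    matches = 0
    for (ta, tb), (qa, qb) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(ta, tb), range(qa, qb)):
            if a[i] == b[j]:
                matches += 1
    n_columns = aln.shape[1]
    return matches / n_columns if n_columns else 0.0


def reduce_redundancy(
    records,
    identity_threshold: float = DEFAULT_IDENTITY,
    keep_ids=None,
) -> list[ProteinRecord]:
    """Greedy redundancy reduction at a pairwise-identity threshold.

    Candidates are visited longest-first (ties by lexicographic id); a record
    is kept iff its identity to every already-kept record is strictly below
    ``identity_threshold``. If ``keep_ids`` (a precomputed set of
    representative ids, e.g. from an external clustering run) is given, the
    greedy step is skipped and those records are returned in input order.
    """
    if keep_ids is not None:
        keep_ids = set(keep_ids)
        return [r for r in records if r.id in keep_ids]
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    kept: list[ProteinRecord] = []
    for rec in ordered:
        if all(
            sequence_identity(rec.sequence, other.sequence) < identity_threshold
            for other in kept
        ):
            kept.append(rec)
    kept_ids = {r.id for r in kept}
    return [r for r in records if r.id in kept_ids]


def extract_windows(record: ProteinRecord, flank: int = DEFAULT_FLANK) -> list[PeptideWindow]:
    """One window per lysine in the sequence, in ascending position order.

    Out-of-range flank positions are filled with ``'-'``; the label is 1 iff
    the K's 1-based position appears in ``record.sites``.
    """
    seq = record.sequence
    site_set = set(record.sites)
    windows = []
    for idx, aa in enumerate(seq):
        if aa != "K":
            continue
        pos = idx + 1
        left = seq[max(0, idx - flank): idx]
        right = seq[idx + 1: idx + 1 + flank]
        residues = "-" * (flank - len(left)) + left + "K" + right + "-" * (flank - len(right))
        windows.append(
            PeptideWindow(
                protein_id=record.id,
                center=pos,
                residues=residues,
                label=int(pos in site_set),
            )
        )
    return windows


def extract_all_windows(records, flank: int = DEFAULT_FLANK) -> list[PeptideWindow]:
    out = []
    for rec in records:
        out.extend(extract_windows(rec, flank=flank))
    return out


def sample_negatives(windows, ratio: int = DEFAULT_NEG_RATIO, seed: int = 0) -> list[PeptideWindow]:
    """Keep every positive window and a uniform random subset of negatives.

    Draws ``min(ratio * n_positives, n_negatives)`` negatives without
    replacement using ``seed``; deterministic for a fixed seed. Output order:
    positives then selected negatives, each in original order.
    """
    positives = [w for w in windows if w.label == 1]
    negatives = [w for w in windows if w.label == 0]
    if not positives:
        raise ValueError("sample_negatives requires at least one positive window")
    n_draw = min(ratio * len(positives), len(negatives))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(negatives), size=n_draw, replace=False))
    return positives + [negatives[i] for i in chosen]


def write_windows(windows, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcenter\tpeptide\tlabel\n")
        for w in windows:
            fh.write(f"{w.protein_id}\t{w.center}\t{w.residues}\t{w.label}\n")


def read_windows(path) -> list[PeptideWindow]:
    windows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "center", "peptide", "label"]:
            raise ValueError(f"{path}: unexpected windows header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, center, peptide, label = line.split("\t")
            windows.append(PeptideWindow(pid, int(center), peptide, int(label)))
    return windows


def build_dataset(
    records,
    site_map,
    flank: int = DEFAULT_FLANK,
    min_length: int = DEFAULT_MIN_LENGTH,
    identity_threshold: float = DEFAULT_IDENTITY,
    neg_ratio: int = DEFAULT_NEG_RATIO,
    seed: int = 0,
    keep_ids=None,
):
    """Full dataset construction: filter, reduce redundancy, window, subsample.

    Returns ``(windows, kept_records)``. Negative subsampling is applied once
    over the whole dataset, after redundancy reduction.
    """
    kept = filter_proteins(records, min_length=min_length)
    kept = attach_sites(kept, site_map)
    kept = reduce_redundancy(kept, identity_threshold=identity_threshold, keep_ids=keep_ids)
    windows = extract_all_windows(kept, flank=flank)
    windows = sample_negatives(windows, ratio=neg_ratio, seed=seed)
    return windows, kept
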