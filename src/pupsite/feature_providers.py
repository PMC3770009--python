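"""Per-residue annotation tracks: conservation, disorder, secondary structure,
solvent accessibility.

Four external predictors supply the tracks in practice — PSI-BLAST (PSSM
profiles), VSL2 (disorder), PSIPRED (secondary structure) and SSPro (two-state
accessibility). This module parses their standard output dialects and, for
pipeline testing without any external runs, provides a deterministic fallback
built from a fixed substitution matrix. Matching writers exist for each dialect
so synthetic datasets can be emitted in the exact layout the parsers consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: Column order of PSSM rows: the PSI-BLAST profile header order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_PSSM_INDEX = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}

SS_LABELS = ("C", "H", "E")
SA_LABELS = ("buried", "exposed")

_DIS_TOL = 1e-6


@dataclass
class ResidueAnnotations:
    """Per-residue annotation tracks for one protein.

    Attributes
    ----------
    pssm : (n, 20) float array
        Conservation log-odds, columns in :data:`PSSM_ALPHABET` order.
    disorder : (n,) float array
        Disorder scores in [0, 1].
    ss : list of str
        Secondary-structure labels, each one of C (coil), H (helix), E (strand).
    sa : list of str
        Two-state solvent accessibility, each "buried" or "exposed".
    """

    pssm: np.ndarray
    disorder: np.ndarray
    ss: list[str]
    sa: list[str]

    def __len__(self) -> int:
        return len(self.disorder)

    def validate(self, sequence: str | None = None) -> None:
        n = len(self)
        if self.pssm.shape != (n, 20):
            raise ValueError(f"pssm shape {self.pssm.shape} != ({n}, 20)")
        if len(self.ss) != n or len(self.sa) != n:
            raise ValueError("annotation track lengths disagree")
        if np.any(self.disorder < 0) or np.any(self.disorder > 1):
            raise ValueError("disorder scores outside [0, 1]")
        bad = set(self.ss) - set(SS_LABELS)
        if bad:
            raise ValueError(f"unknown secondary-structure labels {bad}")
        bad = set(self.sa) - set(SA_LABELS)
        if bad:
            raise ValueError(f"unknown accessibility labels {bad}")
        if sequence is not None and len(sequence) != n:
            raise ValueError(
                f"annotation length {n} != sequence length {len(sequence)}"
            )


def parse_pssm(text: str, sequence: str | None = None) -> np.ndarray:
    """Parse a PSI-BLAST ASCII profile into an (n, 20) log-odds matrix.

    Accepts the `blastpgp -Q` dialect: header lines, then one row per residue
    with index, residue letter, 20 log-odds integers, 20 percentage columns
    and two trailing per-position statistics. Only the first 20 numeric
    columns (the log-odds) are returned, as floats. When ``sequence`` is
    given, residue letters are checked against it.
    """
    rows = []
    letters = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit() or len(parts[1]) != 1 or not parts[1].isalpha():
            continue  # header/footer line
        values = parts[2:]
        if len(values) not in (40, 42):
            raise ValueError(
                f"PSSM line {lineno}: expected 40 score columns (+2 statistics), "
                f"got {len(values)}"
            )
        try:
            rows.append([float(v) for v in values[:20]])
        except ValueError:
            raise ValueError(f"PSSM line {lineno}: non-numeric score column") from None
        letters.append(parts[1].upper())
    if not rows:
        raise ValueError("PSSM file contains no residue rows")
    if sequence is not None:
        for i, (got, want) in enumerate(zip(letters, sequence.upper()), start=1):
            if got != want:
                raise ValueError(
                    f"PSSM residue mismatch at position {i}: file has {got!r}, "
                    f"sequence has {want!r}"
                )
        if len(letters) != len(sequence):
            raise ValueError(
                f"PSSM has {len(letters)} rows but sequence has {len(sequence)} residues"
            )
    return np.asarray(rows, dtype=float)


def write_pssm(pssm: np.ndarray, sequence: str, path) -> None:
    """Write an (n, 20) log-odds matrix in the PSI-BLAST ASCII dialect."""
    pssm = np.asarray(pssm)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(" " * 12 + "  ".join(PSSM_ALPHABET) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, pssm), start=1):
            scores = " ".join(f"{int(round(v)):3d}" for v in row)
            pcts = " ".join("  0" for _ in row)
            fh.write(f"{i:5d} {aa}  {scores} {pcts}  0.00 0.00\n")


def parse_psipred_ss2(text: str) -> list[str]:
    """Parse a PSIPRED ``.ss2`` file into per-residue C/H/E labels."""
    labels = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if len(parts) < 3 or not parts[0].isdigit():
            continue
        label = parts[2]
        if label not in SS_LABELS:
            raise ValueError(f"ss2 line {lineno}: unknown label {label!r}")
        labels.append(label)
    return labels


def write_psipred_ss2(labels, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (synthetic)\n\n")
        for i, (aa, label) in enumerate(zip(sequence, labels), start=1):
            probs = {lab: 0.0 for lab in SS_LABELS}
            probs[label] = 1.0
            fh.write(
                f"{i:4d} {aa} {label}   {probs['C']:.3f}  {probs['H']:.3f}  {probs['E']:.3f}\n"
            )


def parse_disorder(text: str) -> np.ndarray:
    """Parse VSL2-style tabular output into per-residue disorder scores.

    Rows are ``index residue score [label]``. Scores must lie in [0, 1] up to
    a 1e-6 rounding tolerance (and are clipped into range if so); anything
    further out raises.
    """
    scores = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if len(parts) < 3 or not parts[0].isdigit() or len(parts[1]) != 1:
            continue
        try:
            score = float(parts[2])
        except ValueError:
            raise ValueError(f"disorder line {lineno}: non-numeric score {parts[2]!r}") from None
        if score < -_DIS_TOL or score > 1 + _DIS_TOL:
            raise ValueError(f"disorder line {lineno}: score {score} outside [0, 1]")
        scores.append(min(1.0, max(0.0, score)))
    return np.asarray(scores, dtype=float)


def write_disorder(scores, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue disorder scores (synthetic VSL2-style)\n")
        for i, (aa, s) in enumerate(zip(sequence, scores), start=1):
            label = "D" if s >= 0.5 else "."
            fh.write(f"{i}\t{aa}\t{s:.4f}\t{label}\n")


def parse_acc(text: str) -> list[str]:
    """Parse two-state accessibility: a 'b'/'e' string or per-residue rows."""
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith(("#", ">"))]
    labels: list[str] = []
    mapping = {"b": "buried", "e": "exposed", "buried": "buried", "exposed": "exposed"}
    if len(stripped) == 1 and "\t" not in stripped[0] and " " not in stripped[0].strip():
        for i, ch in enumerate(stripped[0].strip(), start=1):
            key = ch.lower()
            if key not in ("b", "e"):
                raise ValueError(f"accessibility string: unknown state {ch!r} at position {i}")
            labels.append(mapping[key])
        return labels
    for lineno, line in enumerate(stripped, start=1):
        token = line.split()[-1].lower()
        if token not in mapping:
            raise ValueError(f"accessibility line {lineno}: unknown state {token!r}")
        labels.append(mapping[token])
    return labels


def write_acc(labels, path) -> None:
    with open(path, "w") as fh:
        fh.write("".join("b" if lab == "buried" else "e" for lab in labels))
        fh.write("\n")


_BLOSUM62 = None


def _blosum62_row(aa: str) -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return np.array([_BLOSUM62[aa, bb] for bb in PSSM_ALPHABET], dtype=float)


def fallback_annotations(sequence: str) -> ResidueAnnotations:
    """Deterministic stand-in annotations for pipeline testing.

    Every residue gets its BLOSUM62 substitution-score row as a pseudo-PSSM
    row (position independent), disorder 0.5, coil secondary structure and
    exposed accessibility. Not a prediction — flagged in the log as fallback.
    """
    logger.info("using fallback annotations (substitution-matrix pseudo-PSSM)")
    n = len(sequence)
    pssm = np.empty((n, 20), dtype=float)
    for i, aa in enumerate(sequence):
        if aa not in _PSSM_INDEX:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        pssm[i] = _blosum62_row(aa)
    return ResidueAnnotations(
        pssm=pssm,
        disorder=np.full(n, 0.5),
        ss=["C"] * n,
        sa=["exposed"] * n,
    )


def write_annotations(ann: ResidueAnnotations, sequence: str, annot_dir, protein_id: str) -> None:
    """Write all four tracks under ``<annot_dir>/<protein_id>.{pssm,ss2,dis,acc}``."""
    from pathlib import Path

    d = Path(annot_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_pssm(ann.pssm, sequence, d / f"{protein_id}.pssm")
    write_psipred_ss2(ann.ss, sequence, d / f"{protein_id}.ss2")
    write_disorder(ann.disorder, sequence, d / f"{protein_id}.dis")
    write_acc(ann.sa, d / f"{protein_id}.acc")


def load_annotations(annot_dir, protein_id: str, sequence: str, fallback: bool = False) -> ResidueAnnotations:
    """Load the four annotation files for one protein from a directory.

    Files follow ``<annot_dir>/<protein_id>.pssm|.ss2|.dis|.acc``. If any file
    is missing and ``fallback`` is true, the deterministic fallback is used
    for the whole protein; otherwise a ``FileNotFoundError`` is raised.
    """
    from pathlib import Path

    d = Path(annot_dir)
    paths = {ext: d / f"{protein_id}.{ext}" for ext in ("pssm", "ss2", "dis", "acc")}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        if fallback:
            return fallback_annotations(sequence)
        raise FileNotFoundError(f"missing annotation files for {protein_id}: {missing}")
    ann = ResidueAnnotations(
        pssm=parse_pssm(paths["pssm"].read_text(), sequence=sequence),
        ss=parse_psipred_ss2(paths["ss2"].read_text()),
        disorder=parse_disorder(paths["dis"].read_text()),
        sa=parse_acc(paths["acc"].read_text()),
    )
    ann.validate(sequence)
    return ann
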