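"""Fixed 646-dimensional encoding of peptide windows.

Each site of a 21-residue window (flank 10) contributes five feature families:

* AAF — the five Atchley amino-acid factors (polarity, secondary-structure
  propensity, molecular volume, codon diversity, electrostatic charge),
  omitted at the centre site because the centre is always lysine;
* PSSM — the residue's 20 conservation log-odds, alphabet ARNDCQEGHILKMFPSTWYV;
* DIS — one structural-disorder score;
* SS — a 3-bit one-hot over coil / helix / strand;
* SA — a 2-bit one-hot over buried / exposed.

That gives 31 features per flanking site and 26 at the centre:
20 × 31 + 26 = 646 at the default flank. Every family of a ``'-'`` padding
position encodes as zeros (so the SS/SA one-hot blocks of a pad sum to 0,
not 1). Feature indices are 1-based and site-major; the within-site order is
AAF, PSSM, DIS, SS (C, H, E), SA (buried, exposed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .feature_providers import PSSM_ALPHABET, SA_LABELS, SS_LABELS, ResidueAnnotations
from .sequence_io import DEFAULT_FLANK, PeptideWindow

FAMILIES = ("AAF", "PSSM", "DIS", "SS", "SA")

#: Atchley factor names, in factor order I..V.
AAF_SUBTYPES = (
    "polarity",
    "secondary-structure",
    "molecular-volume",
    "codon-diversity",
    "electrostatic-charge",
)

# Atchley et al. (2005) solution scores, factors I..V per residue. The five
# factors are standardized transformations of ~500 physicochemical indices:
# across the 20 residues each column has mean 0 and variance ~1.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


def atchley_factors(residue: str) -> tuple[float, float, float, float, float]:
    """Five Atchley factor scores for a residue; ``'-'`` (padding) → five zeros."""
    if residue == "-":
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    try:
        return ATCHLEY_FACTORS[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


@dataclass(frozen=True)
class FeatureDescriptor:
    """Address of one feature: 1-based index, window site, family and subtype."""

    index: int
    site: int
    family: str
    subtype: str


@lru_cache(maxsize=8)
def descriptor_table(flank: int = DEFAULT_FLANK) -> tuple[FeatureDescriptor, ...]:
    """The full, ordered feature-address table for a given flank.

    Site-major (site 1 first); within a site AAF (5, skipped at the centre),
    PSSM (20), DIS (1), SS (C, H, E), SA (buried, exposed). At the default
    flank of 10 this yields 2·10·31 + 26 = 646 descriptors.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    center = flank + 1
    descriptors = []
    index = 1
    for site in range(1, 2 * flank + 2):
        if site != center:
            for name in AAF_SUBTYPES:
                descriptors.append(FeatureDescriptor(index, site, "AAF", name))
                index += 1
        for aa in PSSM_ALPHABET:
            descriptors.append(FeatureDescriptor(index, site, "PSSM", aa))
            index += 1
        descriptors.append(FeatureDescriptor(index, site, "DIS", "score"))
        index += 1
        for lab in SS_LABELS:
            descriptors.append(FeatureDescriptor(index, site, "SS", lab))
            index += 1
        for lab in SA_LABELS:
            descriptors.append(FeatureDescriptor(index, site, "SA", lab))
            index += 1
    return tuple(descriptors)


def n_features(flank: int = DEFAULT_FLANK) -> int:
    return 2 * flank * 31 + 26


def descriptor_tsv(descriptors) -> str:
    lines = ["index\tsite\tfamily\tsubtype"]
    lines += [f"{d.index}\t{d.site}\t{d.family}\t{d.subtype}" for d in descriptors]
    return "\n".join(lines) + "\n"


def write_descriptors(descriptors, path) -> None:
    with open(path, "w") as fh:
        fh.write(descriptor_tsv(descriptors))


def read_descriptors(path) -> tuple[FeatureDescriptor, ...]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "index\tsite\tfamily\tsubtype":
            raise ValueError(f"{path}: unexpected descriptor header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            idx, site, family, subtype = line.split("\t")
            out.append(FeatureDescriptor(int(idx), int(site), family, subtype))
    return tuple(out)


def descriptor_checksum(descriptors) -> str:
    """SHA-256 of the canonical TSV rendering; ties saved models to a layout."""
    return hashlib.sha256(descriptor_tsv(descriptors).encode()).hexdigest()


def encode_window(window: PeptideWindow, annotations: ResidueAnnotations) -> np.ndarray:
    """Encode one window against its source protein's annotation tracks.

    Annotation rows are addressed by protein coordinates: window site ``s``
    maps to protein position ``center + (s - flank - 1)``. Sites whose residue
    is ``'-'`` contribute zeros in every family.
    """
    flank = window.flank
    if len(annotations) and window.center > len(annotations):
        raise ValueError(
            f"window centre {window.center} beyond annotation length {len(annotations)}"
        )
    values = np.zeros(n_features(flank), dtype=float)
    pos = 0
    center_site = flank + 1
    for site, residue in enumerate(window.residues, start=1):
        prot_pos = window.center + (site - center_site)  # 1-based
        is_pad = residue == "-"
        if not is_pad and not 1 <= prot_pos <= len(annotations):
            raise ValueError(
                f"window {window.protein_id}:{window.center} site {site} maps to "
                f"position {prot_pos} outside annotations (length {len(annotations)})"
            )
        if site != center_site:
            if not is_pad:
                values[pos: pos + 5] = atchley_factors(residue)
            pos += 5
        if not is_pad:
            row = annotations.pssm[prot_pos - 1]
            values[pos: pos + 20] = row
            values[pos + 20] = annotations.disorder[prot_pos - 1]
            ss = annotations.ss[prot_pos - 1]
            values[pos + 21 + SS_LABELS.index(ss)] = 1.0
            sa = annotations.sa[prot_pos - 1]
            values[pos + 24 + SA_LABELS.index(sa)] = 1.0
        pos += 26
    assert pos == len(values)
    return values


def encode_dataset(windows, annotations_by_protein) -> tuple[np.ndarray, np.ndarray]:
    """Encode windows into a (n_windows, n_features) matrix plus 0/1 labels.

    Row order follows window order; column order follows
    :func:`descriptor_table`. Raises ``KeyError`` listing every protein id
    that lacks annotations.
    """
    missing = sorted({w.protein_id for w in windows} - set(annotations_by_protein))
    if missing:
        raise KeyError(f"no annotations for proteins: {missing}")
    if not windows:
        return np.zeros((0, n_features()), dtype=float), np.zeros(0, dtype=int)
    flank = windows[0].flank
    X = np.empty((len(windows), n_features(flank)), dtype=float)
    y = np.empty(len(windows), dtype=int)
    for i, w in enumerate(windows):
        X[i] = encode_window(w, annotations_by_protein[w.protein_id])
        y[i] = w.label
    return X, y


def write_feature_matrix(X, y, path) -> None:
    n = X.shape[1]
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(str(i) for i in range(1, n + 1)) + "\n")
        for row, lab in zip(X, y):
            fh.write(str(int(lab)) + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")


def read_feature_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    rows, labels = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            labels.append(int(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=int)
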