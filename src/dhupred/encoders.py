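"""Eleven sequence-derived feature encodings for fixed-length RNA windows.

The schemes fall into three families:

* position-aware encodings — NCP (three chemistry bits per base: ring
  structure, functional group, hydrogen-bond strength), BINARY (one-hot),
  ENAC (sliding-window nucleotide composition), ANF (accumulated nucleotide
  frequency, i.e. prefix density), EIIP (per-base electron-ion interaction
  potential);
* composition encodings — Kmer, RCKmer (reverse-complement-collapsed k-mers),
  NAC/DNC/TNC (k = 1/2/3 fixed);
* PseEIIP — trinucleotide frequencies weighted by summed EIIP potentials.

All encoders are pure functions of the sequence: same input, bit-identical
output.  ``encode_dataset`` applies one scheme to every record of a
:class:`~dhupred.seqio.Dataset` and returns a self-describing
:class:`FeatureMatrix`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .seqio import Dataset, RNA_ALPHABET

__all__ = [
    "ENCODER_NAMES",
    "NCP_CODES",
    "EIIP_VALUES",
    "EncoderSpec",
    "FeatureMatrix",
    "EncodingError",
    "encode_ncp",
    "encode_binary",
    "encode_enac",
    "encode_kmer",
    "encode_nac",
    "encode_dnc",
    "encode_tnc",
    "reverse_complement",
    "canonical_kmer",
    "canonical_kmer_classes",
    "encode_rckmer",
    "encode_anf",
    "encode_eiip",
    "encode_pseeiip",
    "encode_sequence",
    "encode_dataset",
    "feature_dimension",
]

ENCODER_NAMES = (
    "NCP",
    "BINARY",
    "ENAC",
    "Kmer",
    "RCKmer",
    "NAC",
    "DNC",
    "TNC",
    "ANF",
    "EIIP",
    "PseEIIP",
)

# Nucleotide chemistry bits, in order (ring, functional group, hydrogen bond):
# purine {G, A} = 1 vs pyrimidine; amino {C, A} = 1 vs keto;
# weak hydrogen bonding {U, A} = 1 vs strong {G, C}.
NCP_CODES: Mapping[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
}

# One-hot coordinates in fixed nucleotide order A, G, C, U.
BINARY_ORDER = "AGCU"

# Electron-ion interaction potential constants (standard literature values;
# U inherits the T value).  Editable so alternative tables can be configured.
EIIP_VALUES: dict[str, float] = {
    "A": 0.1260,
    "C": 0.1340,
    "G": 0.0806,
    "U": 0.1335,
}

_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: Alphabet in lexicographic order; used for k-mer and composition ordering.
_LEX = "ACGU"


class EncodingError(ValueError):
    """A sequence could not be encoded (bad alphabet or parameters)."""


def _check_alphabet(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise EncodingError(
                f"invalid character {ch!r} at position {i + 1} (1-based)"
            )


def encode_ncp(seq: str) -> np.ndarray:
    """Nucleotide chemical property bits, 3 per position (length 3N)."""
    _check_alphabet(seq)
    out = np.empty(3 * len(seq))
    for i, ch in enumerate(seq):
        out[3 * i : 3 * i + 3] = NCP_CODES[ch]
    return out


def encode_binary(seq: str) -> np.ndarray:
    """One-hot encoding, 4 bits per position in order A, G, C, U (length 4N)."""
    _check_alphabet(seq)
    out = np.zeros(4 * len(seq))
    for i, ch in enumerate(seq):
        out[4 * i + BINARY_ORDER.index(ch)] = 1.0
    return out


def encode_enac(seq: str, w: int = 5) -> np.ndarray:
    """Enhanced nucleic acid composition: per-window base frequencies.

    A window of size ``w`` slides 5'->3' with step 1; each window contributes
    the four nucleotide frequencies (order A, C, G, U), so the output length
    is 4*(N-w+1) and each 4-block sums to 1.
    """
    if w > len(seq):
        raise EncodingError(f"window size {w} exceeds sequence length {len(seq)}")
    if w < 1:
        raise EncodingError("window size must be >= 1")
    _check_alphabet(seq)
    n_win = len(seq) - w + 1
    out = np.empty(4 * n_win)
    for s in range(n_win):
        window = seq[s : s + w]
        for j, ch in enumerate(_LEX):
            out[4 * s + j] = window.count(ch) / w
    return out


def _kmer_index(k: int) -> dict[str, int]:
    return {
        "".join(p): i for i, p in enumerate(itertools.product(_LEX, repeat=k))
    }


def encode_kmer(seq: str, k: int = 3, denom_mode: str = "kmer_count") -> np.ndarray:
    """k-mer frequency vector of length 4^k, lexicographic over A<C<G<U.

    ``denom_mode`` selects the normalisation: ``kmer_count`` (default) divides
    occurrence counts by the number of k-mer positions L-k+1, so entries sum
    to 1; ``seq_length`` divides by the sequence length L.
    """
    if k < 1:
        raise EncodingError("k must be >= 1")
    if k > len(seq):
        raise EncodingError(f"k={k} exceeds sequence length {len(seq)}")
    if denom_mode not in ("kmer_count", "seq_length"):
        raise EncodingError(f"unknown denom_mode {denom_mode!r}")
    _check_alphabet(seq)
    idx = _kmer_index(k)
    counts = np.zeros(4**k)
    for s in range(len(seq) - k + 1):
        counts[idx[seq[s : s + k]]] += 1
    denom = (len(seq) - k + 1) if denom_mode == "kmer_count" else len(seq)
    return counts / denom


def encode_nac(seq: str, denom_mode: str = "kmer_count") -> np.ndarray:
    """Nucleic acid composition (mononucleotide frequencies, length 4)."""
    return encode_kmer(seq, k=1, denom_mode=denom_mode)


def encode_dnc(seq: str, denom_mode: str = "kmer_count") -> np.ndarray:
    """Dinucleotide composition (length 16)."""
    return encode_kmer(seq, k=2, denom_mode=denom_mode)


def encode_tnc(seq: str, denom_mode: str = "kmer_count") -> np.ndarray:
    """Trinucleotide composition (length 64)."""
    return encode_kmer(seq, k=3, denom_mode=denom_mode)


def reverse_complement(seq: str) -> str:
    """Reverse complement under RNA pairing A<->U, C<->G."""
    try:
        return "".join(_RC[ch] for ch in reversed(seq))
    except KeyError as exc:
        raise EncodingError(f"invalid character {exc.args[0]!r}") from None


def canonical_kmer(m: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement; idempotent."""
    rc = reverse_complement(m)
    return m if m <= rc else rc


def canonical_kmer_classes(k: int) -> list[str]:
    """Sorted canonical class representatives (10 classes for k=2, 32 for k=3)."""
    return sorted({canonical_kmer("".join(p)) for p in itertools.product(_LEX, repeat=k)})


def encode_rckmer(seq: str, k: int = 3, denom_mode: str = "kmer_count") -> np.ndarray:
    """Reverse-complement-collapsed k-mer frequencies over canonical classes.

    Strand-symmetric: a sequence and its reverse complement encode identically.
    """
    raw = encode_kmer(seq, k=k, denom_mode=denom_mode)
    classes = canonical_kmer_classes(k)
    class_idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros(len(classes))
    for i, p in enumerate(itertools.product(_LEX, repeat=k)):
        out[class_idx[canonical_kmer("".join(p))]] += raw[i]
    return out


def encode_anf(seq: str) -> np.ndarray:
    """Accumulated nucleotide frequency: density of seq[i] within seq[1..i].

    Entry i (1-based) is the number of occurrences of the base at position i
    within the prefix ending there, divided by i; entries lie in (0, 1] and
    the first entry is always 1.
    """
    _check_alphabet(seq)
    out = np.empty(len(seq))
    counts = {ch: 0 for ch in _LEX}
    for i, ch in enumerate(seq):
        counts[ch] += 1
        out[i] = counts[ch] / (i + 1)
    return out


def encode_eiip(seq: str) -> np.ndarray:
    """Per-position electron-ion interaction potential values (length N)."""
    _check_alphabet(seq)
    return np.array([EIIP_VALUES[ch] for ch in seq])


def encode_pseeiip(seq: str) -> np.ndarray:
    """Pseudo-EIIP: trinucleotide frequencies weighted by summed potentials.

    Entry for trinucleotide xyz is (EIIP_x + EIIP_y + EIIP_z) * f_xyz where
    f_xyz is the trinucleotide frequency over the L-2 positions; 64 entries
    in lexicographic order.
    """
    if len(seq) < 3:
        raise EncodingError("PseEIIP requires sequence length >= 3")
    freqs = encode_kmer(seq, k=3, denom_mode="kmer_count")
    weights = np.array(
        [
            sum(EIIP_VALUES[ch] for ch in "".join(p))
            for p in itertools.product(_LEX, repeat=3)
        ]
    )
    return weights * freqs


# --- scheme registry -------------------------------------------------------


def _names_ncp(n: int, params) -> list[str]:
    props = ("ring", "func", "hbond")
    return [f"pos{i + 1}.{p}" for i in range(n) for p in props]


def _names_binary(n: int, params) -> list[str]:
    return [f"pos{i + 1}.{ch}" for i in range(n) for ch in BINARY_ORDER]


def _names_enac(n: int, params) -> list[str]:
    w = params.get("w", 5)
    return [f"win{s + 1}.{ch}" for s in range(n - w + 1) for ch in _LEX]


def _names_kmer(n: int, params) -> list[str]:
    k = params.get("k", 3)
    return ["".join(p) for p in itertools.product(_LEX, repeat=k)]


def _names_rckmer(n: int, params) -> list[str]:
    return canonical_kmer_classes(params.get("k", 3))


def _names_pos(prefix: str):
    def make(n: int, params) -> list[str]:
        return [f"{prefix}.pos{i + 1}" for i in range(n)]

    return make


_SchemeEntry = tuple[Callable, Callable[[int, dict], list[str]], tuple[str, ...]]

_SCHEMES: dict[str, _SchemeEntry] = {
    "NCP": (encode_ncp, _names_ncp, ()),
    "BINARY": (encode_binary, _names_binary, ()),
    "ENAC": (encode_enac, _names_enac, ("w",)),
    "Kmer": (encode_kmer, _names_kmer, ("k", "denom_mode")),
    "RCKmer": (encode_rckmer, _names_rckmer, ("k", "denom_mode")),
    "NAC": (encode_nac, lambda n, p: list(_LEX), ("denom_mode",)),
    "DNC": (
        encode_dnc,
        lambda n, p: ["".join(q) for q in itertools.product(_LEX, repeat=2)],
        ("denom_mode",),
    ),
    "TNC": (
        encode_tnc,
        lambda n, p: ["".join(q) for q in itertools.product(_LEX, repeat=3)],
        ("denom_mode",),
    ),
    "ANF": (encode_anf, _names_pos("anf"), ()),
    "EIIP": (encode_eiip, _names_pos("eiip"), ()),
    "PseEIIP": (
        encode_pseeiip,
        lambda n, p: ["".join(q) for q in itertools.product(_LEX, repeat=3)],
        (),
    ),
}


@dataclass(frozen=True)
class EncoderSpec:
    """A named encoding scheme plus its scheme-specific parameters.

    Recognised parameters: ``k`` and ``denom_mode`` for the Kmer family,
    ``w`` for ENAC.  Unknown schemes or parameters are rejected eagerly.
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _SCHEMES:
            raise ValueError(
                f"unknown encoder {self.name!r}; valid schemes: "
                f"{', '.join(ENCODER_NAMES)}"
            )
        allowed = _SCHEMES[self.name][2]
        extra = set(self.params) - set(allowed)
        if extra:
            raise ValueError(
                f"{self.name} does not accept parameters {sorted(extra)}"
                + (f"; allowed: {sorted(allowed)}" if allowed else "")
            )
        object.__setattr__(self, "params", dict(self.params))

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderSpec":
        return cls(d["name"], dict(d.get("params", {})))


def encode_sequence(seq: str, spec: EncoderSpec) -> np.ndarray:
    """Apply one encoding scheme to a single sequence."""
    fn = _SCHEMES[spec.name][0]
    return fn(seq, **spec.params)


def feature_dimension(spec: EncoderSpec, length: int) -> int:
    """Feature-vector dimension for the given scheme and sequence length."""
    name, p = spec.name, spec.params
    if name == "NCP":
        return 3 * length
    if name == "BINARY":
        return 4 * length
    if name == "ENAC":
        return 4 * (length - p.get("w", 5) + 1)
    if name == "Kmer":
        return 4 ** p.get("k", 3)
    if name == "RCKmer":
        return len(canonical_kmer_classes(p.get("k", 3)))
    if name == "NAC":
        return 4
    if name == "DNC":
        return 16
    if name in ("TNC", "PseEIIP"):
        return 64
    if name in ("ANF", "EIIP"):
        return length
    raise ValueError(name)


@dataclass(frozen=True)
class FeatureMatrix:
    """n_samples x n_features matrix with encoder identity and feature names."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    encoder: EncoderSpec
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if v.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {v.shape} inconsistent with {len(self.sample_ids)} "
                f"samples x {len(self.feature_names)} features"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write as TSV (first column sample id) plus a JSON sidecar with the spec."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as out:
            out.write("sample_id\t" + "\t".join(self.feature_names) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                out.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        if sidecar:
            with open(path.with_suffix(path.suffix + ".json"), "w") as out:
                json.dump(self.encoder.to_dict(), out, indent=1)
        return path


def encode_dataset(d: Dataset, spec: EncoderSpec) -> FeatureMatrix:
    """Encode every record of a dataset; rows follow record order."""
    rows = []
    for r in d:
        try:
            rows.append(encode_sequence(r.sequence, spec))
        except EncodingError as exc:
            raise EncodingError(f"record {r.id!r}: {exc}") from None
    names = _SCHEMES[spec.name][1](d.length, spec.params)
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(values, tuple(names), spec, d.ids)
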