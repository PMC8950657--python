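"""Benchmark-shaped synthetic datasets with controllable signal.

The generator emulates the composition of the five-species dihydrouridine
benchmark this package targets: 550 windows of 41 nt, 176 positive and 374
negative, with per-species counts H.sapiens 29/68, M.musculus 13/48,
D.melanogaster 9/38, S.cerevisiae 91/93 and E.coli 34/127.  Every window has
U at the centre (the candidate site).  Negatives are drawn from the
background composition; positives carry a position-specific motif on a fixed
window flanking the centre, whose per-position log-odds scale with
``effect_size`` — at 0 the positive and negative distributions are
identical (a null dataset), and the documented large reference value 2.0
gives a strongly recoverable signal.

A ``divergent_species`` can be designated, whose positives use an unrelated
motif; this plants a cross-species generalization failure that the
experiment harness should surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoders import (
    encode_anf,
    encode_binary,
    encode_enac,
    encode_kmer,
    encode_nac,
    encode_ncp,
    encode_rckmer,
)
from .seqio import Dataset, SequenceRecord, write_fasta

__all__ = [
    "TABLE_COMPOSITION",
    "LARGE_EFFECT",
    "SyntheticConfig",
    "generate_dataset",
    "generate_worked_example",
    "write_with_manifest",
]

#: Per-species (positive, negative) counts of the emulated benchmark.
TABLE_COMPOSITION: dict[str, tuple[int, int]] = {
    "H.sapiens": (29, 68),
    "M.musculus": (13, 48),
    "D.melanogaster": (9, 38),
    "S.cerevisiae": (91, 93),
    "E.coli": (34, 127),
}

#: Documented reference effect size for a strongly recoverable motif.
LARGE_EFFECT = 2.0

_BASES = "ACGU"

# Preferred base per motif offset (centre-5 .. centre-1, centre+1 .. centre+5).
_MOTIF_OFFSETS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
_MOTIF_BASES = "GGAGA" "AGAGG"
_DIVERGENT_BASES = "CUCUU" "UUCUC"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults emulate the published benchmark."""

    composition: dict = field(default_factory=lambda: dict(TABLE_COMPOSITION))
    length: int = 41
    effect_size: float = LARGE_EFFECT
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    divergent_species: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1 or self.length % 2 == 0:
            raise ValueError("length must be a positive odd integer")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(n < 0 for pair in self.composition.values() for n in pair):
            raise ValueError("composition counts must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if (
            self.divergent_species is not None
            and self.divergent_species not in self.composition
        ):
            raise ValueError(
                f"divergent species {self.divergent_species!r} not in composition"
            )

    def to_dict(self) -> dict:
        return {
            "composition": {k: list(v) for k, v in self.composition.items()},
            "length": self.length,
            "effect_size": self.effect_size,
            "background": list(self.background),
            "divergent_species": self.divergent_species,
            "seed": self.seed,
        }


def motif_position_probs(
    effect_size: float,
    background: tuple[float, ...],
    preferred: str,
) -> np.ndarray:
    """Base probabilities at one motif position.

    The preferred base receives log-odds ``effect_size`` over the background
    (softmax of log background + effect on the preferred coordinate), so
    effect 0 returns the background exactly.
    """
    logit = np.log(np.asarray(background, dtype=float))
    logit[_BASES.index(preferred)] += effect_size
    w = np.exp(logit - logit.max())
    return w / w.sum()


def _draw_sequence(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    positive: bool,
    motif_bases: str,
) -> str:
    centre = cfg.length // 2
    bg = np.asarray(cfg.background)
    seq = [_BASES[i] for i in rng.choice(4, size=cfg.length, p=bg)]
    seq[centre] = "U"
    if positive and cfg.effect_size > 0:
        for off, pref in zip(_MOTIF_OFFSETS, motif_bases):
            pos = centre + off
            if 0 <= pos < cfg.length and pos != centre:
                probs = motif_position_probs(cfg.effect_size, cfg.background, pref)
                seq[pos] = _BASES[rng.choice(4, p=probs)]
    return "".join(seq)


def generate_dataset(cfg: SyntheticConfig | None = None) -> Dataset:
    """Generate a labelled benchmark-shaped dataset; deterministic per seed."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    records: list[SequenceRecord] = []
    counter = 0
    for species, (n_pos, n_neg) in cfg.composition.items():
        motif = (
            _DIVERGENT_BASES if species == cfg.divergent_species else _MOTIF_BASES
        )
        for label, count in ((1, n_pos), (0, n_neg)):
            for _ in range(count):
                counter += 1
                records.append(
                    SequenceRecord(
                        id=f"syn{counter:04d}",
                        species=species,
                        label=label,
                        sequence=_draw_sequence(rng, cfg, label == 1, motif),
                    )
                )
    return Dataset(tuple(records), cfg.length)


def write_with_manifest(d: Dataset, cfg: SyntheticConfig, out_dir) -> tuple[Path, Path]:
    """Emit the FASTA plus a JSON manifest of the generating configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = write_fasta(d, out_dir / "synthetic.fasta")
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as out:
        json.dump(cfg.to_dict(), out, indent=1)
    return fasta, manifest


def generate_worked_example() -> dict[str, dict[str, np.ndarray]]:
    """Frozen toy sequences with their expected encodings.

    These are the worked vectors used throughout the encoder tests: the
    canonical "GAGACU" example, homopolymers, and a reverse-complement pair
    for the strand-collapsed k-mer scheme.  Values are recomputed here from
    the encoder functions at import of the fixture — the hand-derived
    copies live in the test suite, which is where they are asserted.
    """
    return {
        "GAGACU": {
            "NCP": encode_ncp("GAGACU"),
            "BINARY": encode_binary("GAGACU"),
            "NAC": encode_nac("GAGACU"),
            "ANF": encode_anf("GAGACU"),
        },
        "AAAAA": {"ENAC": encode_enac("AAAAA", w=5)},
        "UU": {"RCKmer": encode_rckmer("UU", k=2)},
        "AA": {"RCKmer": encode_rckmer("AA", k=2)},
        "AAAA": {"Kmer": encode_kmer("AAAA", k=2)},
    }
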