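"""Path-based (Daylight-style) and circular (ECFP4-style) fingerprints
with Tanimoto distances, used to rank analog search hits and to relate
chemical distance to docking-score change.

Distances are 1 - Tanimoto similarity, so 0 = identical bitsets and
low values mean similar molecules.  Fingerprints are folded binary
vectors with deterministic hashing, so results are stable across runs
and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemio import MoleculeRecord

__all__ = [
    "Fingerprint",
    "path_fingerprint",
    "circular_fingerprint",
    "tanimoto_distance",
]


@dataclass(frozen=True)
class Fingerprint:
    kind: str  # "path" or "circular-r{radius}"
    nbits: int
    bits: DataStructs.ExplicitBitVect

    def popcount(self) -> int:
        return int(self.bits.GetNumOnBits())


def path_fingerprint(rec: MoleculeRecord, max_path: int = 7, nbits: int = 2048) -> Fingerprint:
    """Hashed enumeration of linear bond paths up to ``max_path`` bonds
    (Daylight-style topological fingerprint)."""
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=max_path, fpSize=nbits)
    return Fingerprint(kind="path", nbits=nbits, bits=gen.GetFingerprint(rec.mol))


def circular_fingerprint(rec: MoleculeRecord, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Circular atom-environment fingerprint; radius 2 is the ECFP4
    parameterization."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return Fingerprint(kind=f"circular-r{radius}", nbits=nbits, bits=gen.GetFingerprint(rec.mol))


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - |a AND b| / |a OR b|, in [0, 1]."""
    if a.kind != b.kind or a.nbits != b.nbits:
        raise ValueError(f"fingerprint mismatch: {a.kind}/{a.nbits} vs {b.kind}/{b.nbits}")
    return 1.0 - DataStructs.TanimotoSimilarity(a.bits, b.bits)
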