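"""Chemical-graph fingerprints, Tanimoto similarity and chemotype novelty.

Fingerprints are hashed circular (Morgan/ECFP) bit vectors, radius 2 and
4096 bits by default (ECFP4), computed with RDKit after canonicalization
so input atom order is irrelevant.  Novelty of a candidate against a
reference set is the maximum Tanimoto coefficient over the references; a
compound is called novel when that maximum is strictly below the
threshold (default 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .molio import Molecule

DEFAULT_LENGTH = 4096
DEFAULT_RADIUS = 2
DEFAULT_NOVELTY_THRESHOLD = 0.4


@dataclass
class BitFingerprint:
    """A fixed-length hashed fingerprint for one molecule."""

    bits: np.ndarray
    radius: int
    molecule_id: str

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        n = self.bits.shape[0]
        if n <= 0 or (n & (n - 1)) != 0:
            raise ValueError("fingerprint length must be a positive power of two")

    def __len__(self) -> int:
        return self.bits.shape[0]

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstr: str, radius: int, molecule_id: str
                 ) -> "BitFingerprint":
        packed = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
        return cls(np.unpackbits(packed).astype(bool), radius, molecule_id)


@dataclass(frozen=True)
class NoveltyReport:
    query_id: str
    nearest_reference_id: str
    max_tanimoto: float
    novel: bool


def ecfp4(molecule: Molecule | Chem.Mol | str, length: int = DEFAULT_LENGTH,
          radius: int = DEFAULT_RADIUS, molecule_id: str | None = None
          ) -> BitFingerprint:
    """Hashed Morgan fingerprint of the given radius folded to ``length`` bits.

    Accepts a :class:`Molecule`, an RDKit Mol, or a SMILES string.  The
    molecule is canonicalized (SMILES round-trip) before hashing, so two
    representations of the same graph always yield identical bits.
    """
    if isinstance(molecule, Molecule):
        mol, mol_id = molecule.to_rdkit(), molecule.id
    elif isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"invalid SMILES {molecule!r}")
        mol_id = molecule
    else:
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(molecule))
        if mol is None:
            raise ValueError("unparseable molecule")
        mol_id = molecule.GetProp("_Name") if molecule.HasProp("_Name") else ""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(length, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return BitFingerprint(bits=bits, radius=radius,
                          molecule_id=molecule_id or mol_id)


def tanimoto(a: BitFingerprint | np.ndarray, b: BitFingerprint | np.ndarray
             ) -> float:
    """Tanimoto coefficient |A n B| / |A u B| of two equal-length bit sets.

    Two all-zero vectors are identical, so their similarity is 1.
    """
    av = a.bits if isinstance(a, BitFingerprint) else np.asarray(a, dtype=bool)
    bv = b.bits if isinstance(b, BitFingerprint) else np.asarray(b, dtype=bool)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape[0]} vs {bv.shape[0]}")
    union = int(np.logical_or(av, bv).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(av, bv).sum()) / union


def bulk_tanimoto(fps: Sequence[BitFingerprint | np.ndarray]) -> np.ndarray:
    """All-pairs Tanimoto similarity matrix, vectorized over the bit matrix."""
    mat = np.stack([f.bits if isinstance(f, BitFingerprint) else np.asarray(f)
                    for f in fps]).astype(np.int64)
    inter = mat @ mat.T
    pops = mat.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def novelty(query: Molecule | BitFingerprint,
            reference: Sequence[Molecule | BitFingerprint],
            threshold: float = DEFAULT_NOVELTY_THRESHOLD,
            length: int = DEFAULT_LENGTH,
            radius: int = DEFAULT_RADIUS) -> NoveltyReport:
    """Chemotype-novelty call: max Tanimoto against the reference set.

    ``novel`` is true iff the maximum similarity is strictly below the
    threshold.  Ties for the nearest reference break by list order.
    """
    if len(reference) == 0:
        raise ValueError("reference set must be non-empty")
    qfp = query if isinstance(query, BitFingerprint) else ecfp4(query, length, radius)
    best_tc, best_id = -1.0, ""
    for ref in reference:
        rfp = ref if isinstance(ref, BitFingerprint) else ecfp4(ref, length, radius)
        tc = tanimoto(qfp, rfp)
        if tc > best_tc:
            best_tc, best_id = tc, rfp.molecule_id
    return NoveltyReport(query_id=qfp.molecule_id, nearest_reference_id=best_id,
                         max_tanimoto=best_tc, novel=best_tc < threshold)
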