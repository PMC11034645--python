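"""Dense similarity networks: protein sequence and drug structure.

Protein-protein similarity uses Smith-Waterman local alignment scores
(BLOSUM50, affine gaps) normalized by the geometric mean of the two
self-alignment scores so entries land in [0, 1].  Drug-drug similarity is the
Dice coefficient of Morgan-fingerprint bit-sets (radius 2); fingerprint
generation from SMILES is an optional adapter so the core needs no
cheminformatics dependency.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .graph import ProbAdjacency, RelationSpec

__all__ = [
    "smith_waterman_score",
    "protein_similarity_matrix",
    "dice_similarity",
    "drug_similarity_matrix",
    "morgan_fingerprints_from_smiles",
    "read_fasta",
    "read_fingerprints",
]

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


def _aligner(substitution: str | object, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if isinstance(substitution, str):
        substitution = substitution_matrices.load(substitution)
    aligner.substitution_matrix = substitution
    # a gap of length L costs gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman_score(
    seq_a: str,
    seq_b: str,
    substitution: str | object = "BLOSUM50",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Best local-alignment score between two amino-acid sequences.

    Returns 0 when either sequence is empty or no positive-scoring local
    alignment exists.  Residues absent from the substitution table are
    rejected.
    """
    aligner = _aligner(substitution, gap_open, gap_extend)
    alphabet = set(str(c) for c in aligner.substitution_matrix.alphabet)
    for seq in (seq_a, seq_b):
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"residues {sorted(bad)!r} not in the substitution table")
    if not seq_a or not seq_b:
        return 0.0
    return max(0.0, float(aligner.score(seq_a, seq_b)))


def protein_similarity_matrix(
    sequences: Mapping[str, str] | Sequence[str],
    spec: Optional[RelationSpec] = None,
    substitution: str | object = "BLOSUM50",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    normalize: bool = True,
) -> np.ndarray | ProbAdjacency:
    """Pairwise sequence-similarity grid.

    Entry ``[i, j]`` is ``SW(i, j) / sqrt(SW(i, i) * SW(j, j))`` (raw scores
    when ``normalize`` is off, at which point the grid is not a probability
    grid).  Symmetric with unit diagonal.  ``sequences`` is either an ordered
    mapping ``protein_id -> sequence`` or a plain sequence list; a missing or
    empty sequence is rejected.
    """
    if isinstance(sequences, Mapping):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    if any(not s for s in seqs):
        raise ValueError("every protein needs a non-empty sequence")
    n = len(seqs)
    grid = np.zeros((n, n))
    self_scores = np.array(
        [
            smith_waterman_score(s, s, substitution, gap_open, gap_extend)
            for s in seqs
        ]
    )
    if normalize and np.any(self_scores <= 0):
        raise ValueError("non-positive self-alignment score; cannot normalize")
    for i in range(n):
        grid[i, i] = 1.0 if normalize else self_scores[i]
        for j in range(i + 1, n):
            s = smith_waterman_score(seqs[i], seqs[j], substitution, gap_open, gap_extend)
            if normalize:
                s = s / float(np.sqrt(self_scores[i] * self_scores[j]))
            grid[i, j] = grid[j, i] = s
    if spec is not None:
        return ProbAdjacency(spec, grid, np.ones_like(grid, dtype=bool))
    return grid


def dice_similarity(a: frozenset | set, b: frozenset | set) -> float:
    """Dice coefficient ``2|A∩B| / (|A| + |B|)`` of two bit-index sets."""
    if not a and not b:
        warnings.warn("Dice similarity of two empty fingerprints defined as 0")
        return 0.0
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def drug_similarity_matrix(
    fingerprints: Mapping[str, set] | Sequence[set],
    spec: Optional[RelationSpec] = None,
) -> np.ndarray | ProbAdjacency:
    """Pairwise Dice-similarity grid over fingerprint bit-sets.

    Diagonal is 1 for non-empty fingerprints (0, with a warning, for empty
    ones).
    """
    if isinstance(fingerprints, Mapping):
        fps = [set(v) for v in fingerprints.values()]
    else:
        fps = [set(v) for v in fingerprints]
    n = len(fps)
    grid = np.zeros((n, n))
    for i in range(n):
        grid[i, i] = dice_similarity(fps[i], fps[i])
        for j in range(i + 1, n):
            grid[i, j] = grid[j, i] = dice_similarity(fps[i], fps[j])
    if spec is not None:
        return ProbAdjacency(spec, grid, np.ones_like(grid, dtype=bool))
    return grid


def morgan_fingerprints_from_smiles(
    smiles: Mapping[str, str],
    radius: int = 2,
    n_bits: int = 2048,
) -> dict[str, frozenset]:
    """Optional RDKit adapter: SMILES -> Morgan fingerprint on-bit sets.

    Imported lazily so the rest of the package works without RDKit.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError("RDKit is required for fingerprint generation") from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out: dict[str, frozenset] = {}
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for drug {drug_id!r}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        out[drug_id] = frozenset(fp.GetOnBits())
    return out


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ordered ``id -> sequence`` mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_fingerprints(path: str) -> dict[str, frozenset]:
    """Read ``drug_id<TAB>comma-separated-bit-indices`` TSV into bit-sets."""
    out: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            drug_id, bits = line.split("\t")
            out[drug_id] = frozenset(int(b) for b in bits.split(",") if b != "")
    return out
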