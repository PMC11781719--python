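"""Similarity matrices over drugs and proteins.

Four drug views and three protein views feed the diffusion stage:

* drug-drug interaction profiles, drug-disease profiles and drug-side-effect
  profiles, each turned into a drug x drug matrix with the Jaccard
  coefficient J = M11 / (M11 + M01 + M10) over the binary association
  profiles (rows of the relation tables);
* drug structural similarity (Tanimoto over fingerprint bit-vectors, which
  on binary vectors is exactly the Jaccard coefficient);
* protein-protein and protein-disease profiles, again via Jaccard;
* protein genomic similarity: Smith-Waterman local-alignment scores
  normalized by the geometric mean of the self-alignment scores.

A Hamming variant ((M11 + M00) / L, the fraction of agreeing positions)
can replace Jaccard for every profile-derived view; structure and genome
views are unaffected by that switch.
"""

from __future__ import annotations

from typing import Dict, Mapping, NamedTuple, Sequence

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

PROFILE_METRICS = ("jaccard", "hamming")


class ContingencyCounts(NamedTuple):
    """Tuple counts between two equal-length binary profiles."""

    m11: int
    m10: int
    m01: int
    m00: int


def _as_binary(vec) -> np.ndarray:
    arr = np.asarray(vec)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("profile entries must be 0/1")
    return arr.astype(np.int64)


def contingency(a, b) -> ContingencyCounts:
    """Count (1,1), (1,0), (0,1) and (0,0) positions of two binary profiles."""
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"profile lengths differ: {a.shape} vs {b.shape}")
    m11 = int(np.sum((a == 1) & (b == 1)))
    m10 = int(np.sum((a == 1) & (b == 0)))
    m01 = int(np.sum((a == 0) & (b == 1)))
    m00 = int(np.sum((a == 0) & (b == 0)))
    return ContingencyCounts(m11, m10, m01, m00)


def jaccard(a, b) -> float:
    """Jaccard coefficient M11 / (M11 + M01 + M10); 0 if both profiles empty."""
    c = contingency(a, b)
    denom = c.m11 + c.m01 + c.m10
    if denom == 0:
        return 0.0
    return c.m11 / denom


def hamming_similarity(a, b) -> float:
    """Fraction of agreeing positions, (M11 + M00) / L."""
    c = contingency(a, b)
    length = c.m11 + c.m10 + c.m01 + c.m00
    if length == 0:
        raise ValueError("profiles must have nonzero length")
    return (c.m11 + c.m00) / length


def tanimoto(a, b) -> float:
    """Tanimoto score of two fingerprint bit-vectors.

    On binary vectors this is definitionally the Jaccard coefficient.
    """
    return jaccard(a, b)


# ---------------------------------------------------------------------------
# sequence similarity

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


def smith_waterman_score(
    a: str,
    b: str,
    *,
    substitution_matrix=_BLOSUM62,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal local-alignment score under an affine gap penalty.

    A gap of length n costs ``gap_open + (n - 1) * gap_extend``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sa = bseq.ProteinSequence(a)
    sb = bseq.ProteinSequence(b)
    alignments = balign.align_optimal(
        sa, sb, substitution_matrix,
        gap_penalty=(-abs(gap_open), -abs(gap_extend)),
        local=True, max_number=1,
    )
    return float(alignments[0].score)


def smith_waterman_normalized(
    a: str,
    b: str,
    *,
    substitution_matrix=_BLOSUM62,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """SW(a,b) / sqrt(SW(a,a) * SW(b,b)), clipped into [0, 1].

    The geometric-mean self-score normalization makes identical sequences
    score exactly 1 and is symmetric in its arguments.
    """
    kwargs = dict(
        substitution_matrix=substitution_matrix,
        gap_open=gap_open, gap_extend=gap_extend,
    )
    saa = smith_waterman_score(a, a, **kwargs)
    sbb = smith_waterman_score(b, b, **kwargs)
    if saa <= 0 or sbb <= 0:
        raise ValueError("self-alignment score is non-positive under this scoring")
    sab = smith_waterman_score(a, b, **kwargs)
    return float(np.clip(sab / np.sqrt(saa * sbb), 0.0, 1.0))


def sequence_similarity_matrix(
    sequences: Mapping[str, str],
    ids: Sequence[str],
    **kwargs,
) -> np.ndarray:
    """Pairwise normalized Smith-Waterman matrix over *ids*, diagonal 1."""
    n = len(ids)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = smith_waterman_normalized(
                sequences[ids[i]], sequences[ids[j]], **kwargs
            )
    return sim


# ---------------------------------------------------------------------------
# profile similarity matrices (vectorized)


def profile_similarity_matrix(table: np.ndarray, metric: str = "jaccard") -> np.ndarray:
    """Pairwise similarity of the rows of a binary relation table.

    The diagonal is set to 1 for rows with at least one association and 0
    for all-zero rows (an empty profile carries no evidence of
    self-similarity).
    """
    if metric not in PROFILE_METRICS:
        raise ValueError(f"metric must be one of {PROFILE_METRICS}")
    B = _as_binary(table).astype(float)
    n, length = B.shape
    inter = B @ B.T
    row_sums = B.sum(axis=1)
    if metric == "jaccard":
        union = row_sums[:, None] + row_sums[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    else:
        if length == 0:
            raise ValueError("profiles must have nonzero length")
        disagreements = row_sums[:, None] + row_sums[None, :] - 2.0 * inter
        sim = (length - disagreements) / length
    np.fill_diagonal(sim, np.where(row_sums > 0, 1.0, 0.0))
    return sim


def fingerprint_similarity_matrix(
    fingerprints: Mapping[str, np.ndarray],
    ids: Sequence[str],
) -> np.ndarray:
    """Pairwise Tanimoto matrix over fingerprint bit-vectors."""
    table = np.vstack([fingerprints[name] for name in ids])
    return profile_similarity_matrix(table, metric="jaccard")


# ---------------------------------------------------------------------------
# view assembly


def build_similarity_views(
    net,
    *,
    drug_structure: np.ndarray | None = None,
    protein_genome: np.ndarray | None = None,
    profile_metric: str = "jaccard",
) -> tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Assemble the per-class similarity views that feed diffusion.

    Profile-derived views (interaction, disease, side-effect profiles) use
    *profile_metric*; the structure and genome views are passed through
    unchanged when supplied.  Returns ``(drug_views, protein_views)`` as
    ordered name -> matrix dicts.
    """
    rel = net.relations
    drug_views: Dict[str, np.ndarray] = {
        "interaction": profile_similarity_matrix(rel["drug_drug"], profile_metric),
        "disease": profile_similarity_matrix(rel["drug_disease"], profile_metric),
        "sideeffect": profile_similarity_matrix(rel["drug_sideeffect"], profile_metric),
    }
    if drug_structure is not None:
        drug_views["structure"] = np.asarray(drug_structure, dtype=float)
    protein_views: Dict[str, np.ndarray] = {
        "interaction": profile_similarity_matrix(rel["protein_protein"], profile_metric),
        "disease": profile_similarity_matrix(rel["protein_disease"], profile_metric),
    }
    if protein_genome is not None:
        protein_views["genome"] = np.asarray(protein_genome, dtype=float)
    return drug_views, protein_views
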