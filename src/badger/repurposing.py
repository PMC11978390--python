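"""Attention- and signature-based drug-repurposing screen.

Candidates are compared with a reference drug on four criteria, each in
[0,1]: overlap of highly attended pathways, similarity of highly attended
fragments (Tanimoto), and overlap of the top up- and down-regulated gene
sets.  Candidates are ranked by the arithmetic mean of the four and
anti-cancer drugs (name ending in "ib", or an explicit annotation) are
excluded from the shortlist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import featurize as fz
from .network import Badger, pathway_association_scores

__all__ = [
    "RepurposingScore", "attended_pathway_set", "attended_fragment_set",
    "set_jaccard", "fragment_similarity", "deg_overlap_similarity",
    "composite_score", "classify_anticancer", "screen_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class RepurposingScore:
    """One screening-table row: the four criteria and their mean."""

    drug_name: str
    pathway_sim: float
    fragment_sim: float
    up_sim: float
    down_sim: float
    average: float
    is_anticancer: bool
    evidence_note: Optional[str] = None


def attended_pathway_set(A: np.ndarray, threshold: float,
                         pathway_ids: Optional[Sequence[str]] = None
                         ) -> set:
    """Pathways whose aggregate real-fragment attention exceeds the
    threshold.  Returns pathway ids when given, else row indices."""
    A = np.asarray(A, dtype=float)
    k = A.shape[1] - 1
    scores = pathway_association_scores(A, k)
    hits = np.flatnonzero(scores > threshold)
    if pathway_ids is not None:
        return {pathway_ids[i] for i in hits}
    return set(hits.tolist())


def attended_fragment_set(A: np.ndarray, threshold: float) -> set[int]:
    """Real fragments whose maximum attention over pathways exceeds the
    threshold; the pseudo-fragment column is never included."""
    A = np.asarray(A, dtype=float)
    col_max = A[:, :-1].max(axis=0)
    return set(np.flatnonzero(col_max > threshold).tolist())


def set_jaccard(set_a: set, set_b: set) -> float:
    """|A∩B| / |A∪B|; two empty sets score 0 by convention."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def fragment_similarity(fps_a: np.ndarray, attended_a: set[int],
                        fps_b: np.ndarray, attended_b: set[int]) -> float:
    """Symmetrized mean-best-match Tanimoto over attended fragments."""
    if not attended_a or not attended_b:
        logger.warning("empty attended fragment set; fragment similarity 0")
        return 0.0
    a_rows = [fps_a[i] for i in sorted(attended_a)]
    b_rows = [fps_b[j] for j in sorted(attended_b)]
    sim = np.array([[fz.tanimoto(a, b) for b in b_rows] for a in a_rows])
    return float(0.5 * (sim.max(axis=1).mean() + sim.max(axis=0).mean()))


def _top_set(profile: np.ndarray, n_top: int, direction: str) -> set[int]:
    s = 1.0 if direction == "up" else -1.0
    vals = s * np.asarray(profile, dtype=float)
    order = np.lexsort((np.arange(len(vals)), -vals))
    return set(order[:n_top].tolist())


def deg_overlap_similarity(profile_a: np.ndarray, profile_b: np.ndarray,
                           n_top: int = 200, direction: str = "up") -> float:
    """Jaccard overlap of the two profiles' top-``n_top`` gene sets in the
    given direction (signed values, gene-index tie-break)."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or n_top > len(a):
        raise ValueError("profiles must share length, with n_top <= length")
    return set_jaccard(_top_set(a, n_top, direction),
                       _top_set(b, n_top, direction))


def composite_score(pathway_sim: float, fragment_sim: float,
                    up_sim: float, down_sim: float) -> float:
    """Arithmetic mean of the four criteria (full precision; output tables
    format it to 4 decimals)."""
    parts = (pathway_sim, fragment_sim, up_sim, down_sim)
    if any(not 0.0 <= p <= 1.0 for p in parts):
        raise ValueError("all components must be in [0,1]")
    return float(np.mean(parts))


def classify_anticancer(drug_name: str,
                        annotation_map: Optional[Mapping[str, bool]] = None
                        ) -> bool:
    """Explicit annotation wins; otherwise the kinase-inhibitor suffix
    convention applies (lowercase name ending in "ib")."""
    if not drug_name:
        raise ValueError("drug name must be nonempty")
    if annotation_map and drug_name in annotation_map:
        return bool(annotation_map[drug_name])
    return drug_name.lower().endswith("ib")


def screen_candidates(reference_drug: tuple[str, str],
                      candidate_list: Sequence[tuple[str, str]],
                      model: Badger, basal_profile, anchor_profiles,
                      attn_threshold: Optional[float] = None,
                      n_top: int = 200, top_n: int = 10,
                      anticancer_annotations: Optional[Mapping[str, bool]] = None,
                      ) -> tuple[list[RepurposingScore], list[RepurposingScore]]:
    """Screen (name, SMILES) candidates against a reference drug in a fixed
    cell context.

    Each drug is run through the model against the same cell; the four
    similarity criteria against the reference are averaged and candidates
    sorted by the average descending (name ascending tie-break).  Returns
    ``(full_table, shortlist)`` where the shortlist is the top ``top_n``
    non-anticancer candidates.  The attention threshold defaults per drug
    to 1/(k+1), the uniform-attention baseline.  Unparseable candidates are
    skipped with a warning.
    """
    if model.config.use_ppab is False:
        raise ValueError("screening requires the pathway attention block")

    def profile_of(smiles: str):
        frag = fz.featurize_molecule(smiles, n_bits=model.config.n_bits)
        sim = fz.cell_similarity_vector("ctx", basal_profile, anchor_profiles)
        out = model.predict(frag.fingerprints, sim.values)
        thr = attn_threshold if attn_threshold is not None \
            else 1.0 / (frag.k + 1)
        return {
            "frag": frag,
            "profile": out.predicted_profile,
            "pathways": attended_pathway_set(out.attention, thr),
            "fragments": attended_fragment_set(out.attention, thr),
        }

    ref_name, ref_smiles = reference_drug
    ref = profile_of(ref_smiles)
    table = []
    for name, smiles in candidate_list:
        try:
            cand = profile_of(smiles)
        except fz.InvalidMoleculeError as exc:
            logger.warning("skipping candidate %s: %s", name, exc)
            continue
        psim = set_jaccard(ref["pathways"], cand["pathways"])
        fsim = fragment_similarity(
            ref["frag"].fingerprints, ref["fragments"],
            cand["frag"].fingerprints, cand["fragments"])
        up = deg_overlap_similarity(ref["profile"], cand["profile"],
                                    n_top, "up")
        down = deg_overlap_similarity(ref["profile"], cand["profile"],
                                      n_top, "down")
        table.append(RepurposingScore(
            drug_name=name, pathway_sim=round(psim, 4),
            fragment_sim=round(fsim, 4), up_sim=round(up, 4),
            down_sim=round(down, 4),
            average=composite_score(psim, fsim, up, down),
            is_anticancer=classify_anticancer(name, anticancer_annotations)))
    table.sort(key=lambda r: (-r.average, r.drug_name))
    shortlist = [r for r in table if not r.is_anticancer][:top_n]
    return table, shortlist
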