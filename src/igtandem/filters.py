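"""Design selection machinery: TM-score, composite confidence score,
structure-prediction agreement and convergence filters, per-position
fragment-quality filter, ensemble RMSF and structural similarity networks.

The composite score multiplies pTM, mean pLDDT (normalized to 0-1) and the
TM-score of the prediction to the design, averaged over the top-3 models by
mean pLDDT; designs scoring <= 0.6 are discarded and > 0.7 selected.  The
agreement filter requires high-confidence predictions (mean pLDDT above a
cutoff) within an RMSD bound of the design, with a convergence mode that
demands it of all five models.  All filters are pure functions of their
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import superpose, apply_rigid
from .structure import StructureModel, ca_rmsd
from .secstruct import detect_sandwich, assign_strands_and_sheets

COMPOSITE_DISCARD = 0.6
COMPOSITE_SELECT = 0.7
PLDDT_CUT = 90.0
RMSD_CUT = 1.0
FRAGMENT_THRESHOLD_PRESETS = {
    "connector_design": 1.0,
    "face_to_face_round1": 1.5,
    "face_to_face_round2": 1.3,
}


@dataclass
class ModelConfidence:
    """Per-model AF2-style confidence."""

    model_id: str
    plddt: np.ndarray | float          # per-residue 0-100 or mean
    ptm: float

    def __post_init__(self):
        arr = np.atleast_1d(np.asarray(self.plddt, dtype=float))
        if np.any(arr < 0) or np.any(arr > 100):
            raise ValueError("pLDDT must be on the 0-100 scale")
        if not 0.0 <= self.ptm <= 1.0:
            raise ValueError("pTM must be in [0, 1]")

    @property
    def mean_plddt(self) -> float:
        return float(np.mean(self.plddt))


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(l_ref: int) -> float:
    if l_ref < 16:
        raise ValueError("TM-score normalization undefined for L_ref < 16")
    return 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8


def tm_from_distances(distances: np.ndarray, l_ref: int) -> float:
    """TM-score for fixed (frozen) superposition distances."""
    d0 = tm_d0(l_ref)
    d = np.asarray(distances, dtype=float)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def tm_score(coords_ref: np.ndarray, coords_model: np.ndarray,
             correspondence: np.ndarray | None = None) -> float:
    """TM-score of a model against a reference over a 1:1 correspondence.

    Maximized by iterative superposition: seed alignments from windows of
    length 4, L/4 and L/2 across the structure, then alternately superpose
    on the residues within the inclusion distance and rescore, keeping the
    best.  An approximation of the full alignment search, adequate for
    same-topology comparisons.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mod = np.asarray(coords_model, dtype=float)
    if correspondence is not None:
        corr = np.asarray(correspondence)
        ref = ref[corr[:, 0]]
        mod = mod[corr[:, 1]]
    if len(ref) != len(mod):
        raise ValueError("tm_score needs equal-length coordinate sets "
                         "(provide a correspondence for unequal models)")
    l_ref = len(ref)
    d0 = tm_d0(l_ref)

    def score_from(window: slice) -> float:
        try:
            R, t, _ = superpose(ref[window], mod[window])
        except ValueError:
            return 0.0
        best = 0.0
        subset = None
        for _ in range(20):
            moved = apply_rigid(mod, R, t)
            d = np.linalg.norm(moved - ref, axis=1)
            best = max(best, tm_from_distances(d, l_ref))
            cut = d0
            new = np.where(d < cut)[0]
            while len(new) < 4:
                cut *= 1.5
                new = np.where(d < cut)[0]
            if subset is not None and np.array_equal(new, subset):
                break
            subset = new
            R, t, _ = superpose(ref[subset], mod[subset])
        return best

    best = 0.0
    for wlen in {4, max(l_ref // 4, 4), max(l_ref // 2, 4), l_ref}:
        for start in range(0, l_ref - wlen + 1, max(wlen // 2, 1)):
            best = max(best, score_from(slice(start, start + wlen)))
    return best


def tm_score_models(model_a: StructureModel, model_b: StructureModel) -> float:
    """Symmetrized TM-score between two models' CA traces."""
    ca_a = model_a.ca_coords()
    ca_b = model_b.ca_coords()
    n = min(len(ca_a), len(ca_b))
    ca_a, ca_b = ca_a[:n], ca_b[:n]
    return 0.5 * (tm_score(ca_a, ca_b) + tm_score(ca_b, ca_a))


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------

def composite_score_single(ptm: float, mean_plddt: float, tm_to_design: float) -> float:
    """pTM x (pLDDT/100) x TM-score for one prediction."""
    if not 0 <= ptm <= 1 or not 0 <= mean_plddt <= 100 or not 0 <= tm_to_design <= 1:
        raise ValueError("inputs outside their declared ranges")
    return ptm * (mean_plddt / 100.0) * tm_to_design


@dataclass
class CompositeResult:
    score: float
    verdict: str               # 'discard' | 'undecided' | 'select'
    n_models: int
    flagged: bool              # fewer than the requested top-k available


def composite_score(records: list[tuple[float, float, float]],
                    top: int = 3, mode: str = "mean",
                    discard_below: float = COMPOSITE_DISCARD,
                    select_above: float = COMPOSITE_SELECT) -> CompositeResult:
    """Composite confidence over predictions (ptm, mean_plddt, tm_to_design).

    Models are ranked by mean pLDDT; the per-model composite values of the
    top ``top`` are aggregated by ``mode`` ('mean', or 'max' as the exposed
    alternative reading).  Verdict: score <= 0.6 discard, > 0.7 select.
    """
    if not records:
        raise ValueError("no prediction records")
    ranked = sorted(records, key=lambda r: -r[1])[:top]
    vals = [composite_score_single(*r) for r in ranked]
    score = float(np.mean(vals) if mode == "mean" else np.max(vals))
    verdict = ("discard" if score <= discard_below
               else "select" if score > select_above else "undecided")
    return CompositeResult(score, verdict, len(ranked), len(records) < top)


# ---------------------------------------------------------------------------
# agreement / convergence filter
# ---------------------------------------------------------------------------

@dataclass
class AgreementVerdict:
    passed: bool
    n_passing: int
    per_model: list[bool]


def af2_agreement_filter(stats: list[dict[str, float]],
                         plddt_cut: float = PLDDT_CUT,
                         rmsd_cut: float = RMSD_CUT,
                         min_passing: int = 1,
                         rmsd_keys: tuple[str, ...] = ("rmsd",)
                         ) -> AgreementVerdict:
    """Prediction-agreement filter.

    Each entry holds 'plddt' (mean) and one or more RMSD components to the
    design; a model passes when pLDDT > plddt_cut and every listed RMSD
    component is < rmsd_cut (strict).  The verdict passes when at least
    ``min_passing`` models pass: 1 reproduces the basic screen, 5 the
    all-model convergence rule, and ``rmsd_keys`` of e.g. ('rmsd_scaffold',
    'rmsd_linker1', 'rmsd_linker2', 'rmsd_motif') with min_passing=4 the
    grafted-design rule (total RMSD excluded).
    """
    if not stats:
        raise ValueError("no models given")
    per = []
    for s in stats:
        ok = s["plddt"] > plddt_cut and all(s[k] < rmsd_cut for k in rmsd_keys)
        per.append(bool(ok))
    n = sum(per)
    return AgreementVerdict(n >= min_passing, n, per)


def agreement_from_models(design: StructureModel,
                          models: list[StructureModel],
                          confidences: list[ModelConfidence],
                          selection=None, **kwargs) -> AgreementVerdict:
    """Convenience wrapper computing CA-RMSDs from structures."""
    stats = [{"plddt": c.mean_plddt,
              "rmsd": ca_rmsd(design, m, selection)}
             for m, c in zip(models, confidences)]
    return af2_agreement_filter(stats, **kwargs)


# ---------------------------------------------------------------------------
# fragment quality
# ---------------------------------------------------------------------------

@dataclass
class FragmentVerdict:
    passed: bool
    failing_positions: list[int]


def fragment_quality_filter(per_position_rmsds: list[list[float]] | dict[int, list[float]],
                            threshold: float = 1.0) -> FragmentVerdict:
    """Local sequence-structure compatibility from 9-mer fragment RMSDs.

    Passes iff at every position at least one picked fragment has RMSD
    strictly below the threshold.  Thresholds of 1.0 / 1.5 / 1.3 Å are the
    named presets in :data:`FRAGMENT_THRESHOLD_PRESETS`.
    """
    if isinstance(per_position_rmsds, dict):
        items = sorted(per_position_rmsds.items())
    else:
        items = list(enumerate(per_position_rmsds))
    if not items:
        raise ValueError("no positions given")
    failing = []
    for pos, vals in items:
        if len(vals) == 0:
            raise ValueError(f"position {pos} has no fragment RMSDs")
        if not np.min(vals) < threshold:
            failing.append(pos)
    return FragmentVerdict(not failing, failing)


# ---------------------------------------------------------------------------
# ensemble RMSF
# ---------------------------------------------------------------------------

@dataclass
class EnsembleStats:
    rmsf: np.ndarray
    distance_traces: dict[str, np.ndarray] = field(default_factory=dict)


def ensemble_rmsf(frames: list[StructureModel],
                  selection=None,
                  atom_pairs: list[tuple[int, str, int, str]] | None = None
                  ) -> EnsembleStats:
    """Per-residue CA fluctuations of a conformational ensemble.

    Frames are superposed on the first frame over ``selection`` before
    computing RMSF_i = sqrt(<|x_i - <x_i>|^2>).  ``atom_pairs`` of
    (residue_number, atom, residue_number, atom) add per-frame distance
    traces (e.g. salt-bridge or chelator-metal distances).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    ref_sel = frames[0].ca_coords(selection)
    n_res = len(frames[0].ca_coords())
    stack = np.empty((len(frames), n_res, 3))
    aligned_frames = []
    for k, fr in enumerate(frames):
        sel = fr.ca_coords(selection)
        if sel.shape != ref_sel.shape or len(fr.ca_coords()) != n_res:
            raise ValueError("frame length mismatch")
        R, t, _ = superpose(ref_sel, sel)
        moved = fr.transformed(R, t)
        aligned_frames.append(moved)
        stack[k] = moved.ca_coords()
    mean = stack.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    traces = {}
    for (num_a, at_a, num_b, at_b) in atom_pairs or []:
        vals = []
        for fr in aligned_frames:
            by_num = {r.residue_number: r for r in fr.residues()}
            pa = by_num[num_a].atom(at_a)
            pb = by_num[num_b].atom(at_b)
            vals.append(float(np.linalg.norm(pa - pb)))
        traces[f"{num_a}{at_a}-{num_b}{at_b}"] = np.array(vals)
    return EnsembleStats(rmsf, traces)


# ---------------------------------------------------------------------------
# similarity network
# ---------------------------------------------------------------------------

def similarity_network(models: list[StructureModel],
                       score_threshold: float = 0.6) -> nx.Graph:
    """Structural similarity network over pairwise TM-scores.

    Nodes are model labels annotated with detected strand counts (and the
    full sandwich strand count where the model is a two-sheet sandwich);
    undirected edges connect pairs with TM-score >= threshold.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    g = nx.Graph()
    labels = []
    for k, m in enumerate(models):
        label = m.label or f"model{k}"
        labels.append(label)
        try:
            strands, _ = assign_strands_and_sheets(m)
            n_strands = len(strands)
        except ValueError:
            n_strands = 0
        g.add_node(label, n_strands=n_strands)
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            tm = tm_score_models(models[i], models[j])
            if tm >= score_threshold:
                g.add_edge(labels[i], labels[j], tm=tm)
    return g
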