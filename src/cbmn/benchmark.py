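"""Match scored cells against generator ground truth.

Used to measure classification accuracy and micronucleus precision/recall on
synthetic plates: a truth cell matches the scored cell whose cytoplasm
territory contains its centre, and MN calls match truth placements by
centroid distance (greedy nearest-pair assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .score import CellObject
from .simulate import CellTruth, GroundTruth


@dataclass
class FieldEvaluation:
    n_truth_cells: int = 0
    n_matched: int = 0
    n_class_correct: int = 0
    mn_true_positive: int = 0
    mn_false_negative: int = 0
    mn_false_positive: int = 0

    def merge(self, other: "FieldEvaluation") -> None:
        for name in vars(self):
            setattr(self, name, getattr(self, name) + getattr(other, name))

    @property
    def classification_accuracy(self) -> float:
        return self.n_class_correct / max(self.n_truth_cells, 1)

    @property
    def mn_precision(self) -> float:
        denom = self.mn_true_positive + self.mn_false_positive
        return self.mn_true_positive / denom if denom else float("nan")

    @property
    def mn_recall(self) -> float:
        denom = self.mn_true_positive + self.mn_false_negative
        return self.mn_true_positive / denom if denom else float("nan")


def _match_cells(cells: list[CellObject], cyto_labels: np.ndarray,
                 truth: GroundTruth) -> list[tuple[CellTruth, CellObject | None]]:
    by_label = {c.cytoplasm_label: c for c in cells}
    pairs = []
    for tc in truth.cells:
        if tc.touches_border:
            continue
        r, c = int(round(tc.center[0])), int(round(tc.center[1]))
        r = min(max(r, 0), cyto_labels.shape[0] - 1)
        c = min(max(c, 0), cyto_labels.shape[1] - 1)
        pairs.append((tc, by_label.get(int(cyto_labels[r, c]))))
    return pairs


def _greedy_match(truth_pts: np.ndarray, call_pts: np.ndarray,
                  tol: float) -> int:
    """Number of truth/call pairs within ``tol`` px (greedy nearest-first)."""
    if truth_pts.size == 0 or call_pts.size == 0:
        return 0
    d = np.linalg.norm(truth_pts[:, None, :] - call_pts[None, :, :], axis=2)
    matched = 0
    used_t: set[int] = set()
    used_c: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ti, ci in order:
        if d[ti, ci] > tol:
            break
        if ti in used_t or ci in used_c:
            continue
        used_t.add(int(ti))
        used_c.add(int(ci))
        matched += 1
    return matched


def evaluate_field(cells: list[CellObject], cyto_labels: np.ndarray,
                   truth: GroundTruth, mn_tol_px: float = 5.0,
                   ) -> FieldEvaluation:
    """Score one field's cell objects against its ground truth."""
    ev = FieldEvaluation()
    matched_calls = 0
    for tc, cell in _match_cells(cells, cyto_labels, truth):
        ev.n_truth_cells += 1
        if cell is None:
            ev.mn_false_negative += len(tc.micronuclei)
            continue
        ev.n_matched += 1
        if cell.classification == tc.cls:
            ev.n_class_correct += 1
        t_pts = np.array([m.center for m in tc.micronuclei], dtype=float)
        c_pts = np.array([m.centroid for m in cell.mn_calls], dtype=float)
        tp = _greedy_match(t_pts.reshape(-1, 2), c_pts.reshape(-1, 2), mn_tol_px)
        ev.mn_true_positive += tp
        ev.mn_false_negative += len(tc.micronuclei) - tp
        matched_calls += tp
    n_calls = sum(len(c.mn_calls) for c in cells)
    ev.mn_false_positive += n_calls - matched_calls
    return ev


def evaluate_fields(per_field: list[tuple[list[CellObject], np.ndarray,
                                          GroundTruth]],
                    mn_tol_px: float = 5.0) -> FieldEvaluation:
    total = FieldEvaluation()
    for cells, cyto, truth in per_field:
        total.merge(evaluate_field(cells, cyto, truth, mn_tol_px))
    return total
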