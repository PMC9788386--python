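"""Cell assembly, micronucleus criteria and endpoint arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbmn import MnParams, SynthParams, assemble_cells, compute_cbpi, \
    compute_endpoints, detect_micronuclei, generate_field
from cbmn.score import CellObject, EndpointError, Micronucleus, score_field
from conftest import toy_disk


def _bnc_scene(mn_specs=()):
    """Toy scene: one cytoplasm with two main nuclei plus optional MN discs.

    mn_specs: iterable of (center, radius, touching_nucleus) placements drawn
    into the DNA channel only (small objects never enter the nucleus map).
    """
    shape = (120, 120)
    dna = np.full(shape, 20.0)
    cyto = np.zeros(shape, dtype=np.int32)
    cyto[toy_disk(shape, (60, 60), 45)] = 1
    nuclei = np.zeros(shape, dtype=np.int32)
    for lab, ctr in ((1, (45, 45)), (2, (75, 45))):
        m = toy_disk(shape, ctr, 10)
        nuclei[m] = lab
        dna[m] = 100.0
    for ctr, r in mn_specs:
        dna[toy_disk(shape, ctr, r)] = 100.0
    return dna, nuclei, cyto


class TestAssembleCells:
    def test_two_interior_nuclei_make_a_bnc(self):
        dna, nuclei, cyto = _bnc_scene()
        cells = assemble_cells(nuclei, cyto, dna)
        assert len(cells) == 1
        assert cells[0].classification == "bi"
        assert cells[0].n_nuclei == 2

    def test_straddling_nucleus_is_cross_contaminating(self):
        shape = (100, 100)
        dna = np.full(shape, 20.0)
        cyto = np.zeros(shape, dtype=np.int32)
        cyto[10:90, 10:50] = 1
        cyto[10:90, 50:90] = 2
        nuclei = np.zeros(shape, dtype=np.int32)
        nuclei[20:30, 20:30] = 1   # interior to territory 1
        nuclei[60:70, 60:70] = 2   # interior to territory 2
        nuclei[40:50, 45:55] = 3   # 50/50 straddler: removed
        dna[nuclei > 0] = 100.0
        cells = assemble_cells(nuclei, cyto, dna)
        assert [c.classification for c in cells] == ["mono", "mono"]
        assert all(n.label != 3 for c in cells for n in c.nuclei)

    def test_shape_mismatch_is_contract_error(self):
        with pytest.raises(ValueError):
            assemble_cells(np.zeros((5, 5), int), np.zeros((6, 6), int),
                           np.zeros((5, 5)))

    def test_noiseless_field_counts_match_truth_exactly(self, noiseless_params):
        fld, truth = generate_field(noiseless_params, 0)
        cells, _ = score_field(fld)
        ep = compute_endpoints(cells)
        assert (ep.n_mono, ep.n_bi, ep.n_multi, ep.n_mn) == \
            (truth.n_mono, truth.n_bi, truth.n_multi, truth.n_mn)


class TestDetectMicronuclei:
    def _detect(self, mn_specs):
        dna, nuclei, cyto = _bnc_scene(mn_specs)
        cells = assemble_cells(nuclei, cyto, dna)
        return detect_micronuclei(cells[0], nuclei, cyto, dna)

    def test_proper_mn_is_accepted(self):
        # diameter ratio 4/20 = 0.2, well separated
        calls = self._detect([((60, 85), 2)])
        assert len(calls) == 1
        assert 1 / 16 < calls[0].diameter_ratio < 1 / 3

    def test_oversized_candidate_is_rejected(self):
        # diameter ratio 10/20 = 0.5 > 1/3
        assert self._detect([((60, 85), 5)]) == []

    def test_candidate_touching_a_nucleus_is_rejected(self):
        # disc adjacent to nucleus 2 (centre 75,45 radius 10)
        assert self._detect([((75, 58), 2)]) == []

    def test_non_bnc_cells_return_empty_by_contract(self):
        dna, nuclei, cyto = _bnc_scene([((60, 85), 2)])
        cells = assemble_cells(nuclei, cyto, dna)
        mono = CellObject(cell_id=1, cytoplasm_label=1,
                          nuclei=cells[0].nuclei[:1], classification="mono")
        assert detect_micronuclei(mono, nuclei, cyto, dna) == []

    def test_synthetic_mn_recovered(self):
        p = SynthParams(seed=13, p_mono=0.0, p_bi=1.0, p_multi=0.0,
                        mn_rate=0.6)
        fld, truth = generate_field(p, 0)
        cells, _ = score_field(fld)
        assert sum(len(c.mn_calls) for c in cells) == truth.n_mn


class TestEndpoints:
    @pytest.mark.parametrize("counts,expected", [
        ((100, 0, 0), 1.0),
        ((0, 100, 0), 2.0),
        ((40, 50, 10), 1.70),
        ((0, 0, 7), 3.0),
    ])
    def test_cbpi_hand_cases(self, counts, expected):
        assert compute_cbpi(*counts) == pytest.approx(expected)

    def test_cbpi_undefined_without_cells(self):
        with pytest.raises(EndpointError):
            compute_cbpi(0, 0, 0)

    def test_mn_rate_arithmetic(self):
        mn = Micronucleus(10.0, 3.5, 0.2, 90.0, (1.0, 1.0))
        cells = [CellObject(i, i, nuclei=[None, None], classification="bi")
                 for i in range(4000)]
        for c in cells[:12]:
            c.mn_calls = [mn]
        ep = compute_endpoints(cells)
        assert ep.mn_per_1000_bnc == pytest.approx(3.0)

    def test_all_mono_gives_floor_values(self):
        cells = [CellObject(i, i, nuclei=[None], classification="mono")
                 for i in range(10)]
        ep = compute_endpoints(cells)
        assert ep.cbpi == 1.0 and ep.pct_bnc == 0.0
        assert ep.qc_flags == "no_bnc" and ep.mn_per_1000_bnc == 0.0

    def test_empty_input_is_flagged(self):
        ep = compute_endpoints([])
        assert ep.n_total_scored == 0 and ep.qc_flags == "no_cells"

    def test_mn_rate_invariant_to_non_bnc_cells(self):
        mn = Micronucleus(10.0, 3.5, 0.2, 90.0, (1.0, 1.0))
        bncs = [CellObject(i, i, nuclei=[None, None], classification="bi",
                           mn_calls=[mn] if i < 3 else [])
                for i in range(50)]
        base = compute_endpoints(bncs).mn_per_1000_bnc
        extra = bncs + [CellObject(99, 99, nuclei=[None],
                                   classification="mono"),
                        CellObject(98, 98, nuclei=[None] * 4,
                                   classification="multi")]
        assert compute_endpoints(extra).mn_per_1000_bnc == base

    @settings(max_examples=60, deadline=None)
    @given(n_mono=st.integers(1, 500), n_bi=st.integers(0, 500),
           n_multi=st.integers(0, 500))
    def test_cbpi_bounds_and_monotonicity(self, n_mono, n_bi, n_multi):
        v = compute_cbpi(n_mono, n_bi, n_multi)
        assert 1.0 <= v <= 3.0
        # reclassifying one mono cell as bi strictly increases the index
        assert compute_cbpi(n_mono - 1, n_bi + 1, n_multi) > v or n_mono == 0
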