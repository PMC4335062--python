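import itertools

import numpy as np
import pytest

from bzipspec.data import Dataset, InteractionRecord
from bzipspec.design import (
    DesignProblem,
    HeptadLibrary,
    assemble,
    assembly_score,
    basis_size,
    build_library,
    composition_constraints,
    decompose,
    design_space_size,
    enumerate_designs,
    junction_rules,
    rare_core_pairs,
    solve_design,
    verify_solution,
)
from bzipspec.features import FeatureKey, encode
from bzipspec.registers import assign_register
from bzipspec.semisvr import WeightModel
from bzipspec.synthetic import SimulationConfig, plant_model, simulate_coils

from conftest import random_coil


@pytest.fixture(scope="module")
def design_world():
    cfg = SimulationConfig(
        n_proteins=30, blocks_per_protein=4, off_alphabet_mass=0.0, seed=3
    )
    coils = simulate_coils(cfg)
    model = plant_model(cfg)
    library = build_library(coils, prefilter=False)
    return coils, model, library


def no_comp(**kw):
    """DesignProblem with all composition rules off unless overridden."""
    defaults = dict(
        max_met_d=None,
        max_polar_a=None,
        his_d_last_only=False,
        glu_a_first_only=False,
        asn_a_nonterminal_only=False,
        n_terminal_entries_first_only=False,
    )
    defaults.update(kw)
    return DesignProblem(**defaults)


class TestBuildLibrary:
    def test_two_block_coil_gives_two_entries_first_flagged(self):
        coil = assign_register("c", "QEKKLLEQDNKAVE", "f")
        lib = build_library([coil], prefilter=False)
        assert len(lib) == 2
        flags = {e.seq: e.n_terminal for e in lib.entries}
        assert flags[coil.block_seq(1)] is True
        assert flags[coil.block_seq(2)] is False

    def test_shared_heptads_deduplicate(self):
        a = assign_register("a", "QEKKLLE" * 2, "f")
        b = assign_register("b", "QEKKLLE" + "RDNAIVD", "f")
        lib = build_library([a, b], prefilter=False)
        assert len({e.seq for e in lib.entries}) == len(lib) == 2

    def test_prefilter_drops_non_canonical_core(self):
        coil = assign_register("c", "QEKKLWE", "f")  # d = Trp
        lib = build_library([coil], prefilter=True)
        assert len(lib) == 0

    def test_combinatorics_of_published_library(self):
        assert design_space_size(1303, 6) == 1303**6
        assert design_space_size(1303, 6) == pytest.approx(5e18, rel=0.03)
        assert basis_size() == 8 * 5 * 5 * 5 == 1000


class TestDecompose:
    def test_within_block_only_model_has_zero_junctions(self, design_world):
        coils, _, library = design_world
        key_model = WeightModel(
            w={FeatureKey("a-a'", (x, y)): 0.3 for x in "LNVI" for y in "LNVI"}
        )
        dec = decompose(key_model, coils[0], library, M=3)
        assert np.all(dec.c == 0.0)
        assert np.any(dec.s != 0.0)

    def test_cross_block_pair_stays_per_block(self, design_world):
        # the d_i - a'_{i+1} pair crosses heptads, but the design chain
        # contributes only ONE residue to it (the a' sits on the fixed
        # partner), so it is a per-block term, not a junction correction
        coils, _, library = design_world
        key_model = WeightModel(
            w={FeatureKey("d-a'+1", (x, y)): 0.3 for x in "LHVMI" for y in "LNVI"}
        )
        dec = decompose(key_model, coils[0], library, M=3)
        assert np.all(dec.c == 0.0)
        assert np.any(dec.s != 0.0)

    def test_spanning_triplet_goes_to_junctions(self, design_world):
        # d_i - a_{i+1} - d'_i puts two design residues (d_i, a_{i+1}) in
        # adjacent f-anchored blocks: junction corrections arise from such
        # triplet terms
        coils, _, library = design_world
        key_model = WeightModel(
            w={
                FeatureKey("d-a+1-d'", (x, y, z)): 0.3
                for x in "LHVMI"
                for y in "LNVIKART"
                for z in "LHVMI"
            }
        )
        dec = decompose(key_model, coils[0], library, M=3)
        assert np.any(dec.c != 0.0)
        # the swapped chain role (design contributing only d'_i) stays in s,
        # so s need not vanish; exactness is covered by the oracle test

    def test_exactness_on_random_assemblies(self, design_world):
        coils, model, library = design_world
        rng = np.random.default_rng(0)
        target = coils[0]
        dec = decompose(model, target, library, M=3)
        sub = target.block_subcoil(1, 3)
        for _ in range(30):
            choice = list(rng.integers(0, len(library), size=3))
            full = model.predict(encode(assemble(library, choice), sub))
            assert assembly_score(dec, choice) == pytest.approx(full, abs=1e-9)


class TestJunctionRules:
    def test_native_adjacencies_are_self_consistent(self, design_world):
        coils, _, _ = design_world
        coil = coils[0]
        lib = build_library([coil], prefilter=False)
        allowed = junction_rules(lib, [coil])
        seqs = [e.seq for e in lib.entries]
        for k in range(1, coil.n_blocks):
            j1 = seqs.index(coil.block_seq(k))
            j2 = seqs.index(coil.block_seq(k + 1))
            assert (j1, j2) in allowed

    def test_unobserved_pair_disallows_junction(self):
        native = assign_register("n", "QEKKLLE" * 2, "f")
        lib = HeptadLibrary(entries=build_library([native], prefilter=False).entries)
        # entry with e=W never occurs before anything in the native coil
        odd = assign_register("o", "QEKKLLW" + "QEKKLLE", "f")
        lib2 = build_library([native, odd], prefilter=False)
        allowed = junction_rules(lib2, [native])
        w_idx = [i for i, e in enumerate(lib2.entries) if e.seq.endswith("W")]
        assert w_idx
        for j in w_idx:
            assert all((j, k) not in allowed for k in range(len(lib2)))

    def test_allowed_set_matches_exhaustive_scan(self, design_world):
        coils, _, _ = design_world
        natives = coils[:5]
        lib = build_library(natives, prefilter=False)
        allowed = junction_rules(lib, natives)
        # oracle: scan every native block junction for each candidate (j,k)
        def observed(j, k):
            ej, ek = lib[j].seq, lib[k].seq
            e_f = d_g = e_a = False
            for c in natives:
                for b in range(1, c.n_blocks):
                    b1, b2 = c.block_seq(b), c.block_seq(b + 1)
                    e_f |= (b1[6], b2[0]) == (ej[6], ek[0])
                    d_g |= (b1[5], b2[1]) == (ej[5], ek[1])
                    e_a |= (b1[6], b2[2]) == (ej[6], ek[2])
            return e_f and d_g and e_a

        for j in range(len(lib)):
            for k in range(len(lib)):
                assert ((j, k) in allowed) == observed(j, k)


class TestSolveDesign:
    def test_single_admissible_heptad_is_forced(self, design_world):
        coils, model, _ = design_world
        lib = HeptadLibrary(entries=build_library([coils[0]], prefilter=False).entries[:1])
        dec = decompose(model, coils[0], lib, M=3)
        prob = no_comp(target=dec, gap=None, off_cutoffs={})
        sol = solve_design(prob, lib)
        assert sol.choice == [0, 0, 0]
        assert sol.sequence == lib[0].seq * 3

    def test_ilp_equals_exhaustive_enumeration(self, design_world):
        coils, model, library = design_world
        lib = HeptadLibrary(entries=library.entries[:5])
        dec = decompose(model, coils[0], lib, M=3)
        prob = no_comp(target=dec, gap=None, off_cutoffs={})
        sol = solve_design(prob, lib)
        choice, best = enumerate_designs(prob, lib)
        assert sol.S_target == pytest.approx(best, abs=1e-9)

    def test_ilp_equals_enumeration_with_constraints(self, design_world):
        coils, model, library = design_world
        lib = HeptadLibrary(entries=library.entries[:6])
        adj = junction_rules(lib, coils)
        dec_t = decompose(model, coils[0], lib, M=3)
        dec_o = decompose(model, coils[1], lib, M=3)
        for gap in (0.0, 0.5):
            prob = no_comp(
                target=dec_t, off_targets=[dec_o], allowed_adjacency=adj, gap=gap
            )
            sol = solve_design(prob, lib)
            choice, best = enumerate_designs(prob, lib)
            if choice is None:
                assert not sol.choice
            else:
                assert sol.S_target == pytest.approx(best, abs=1e-9)

    def test_constraints_never_improve_the_optimum(self, design_world):
        coils, model, library = design_world
        lib = HeptadLibrary(entries=library.entries[:8])
        dec_t = decompose(model, coils[0], lib, M=3)
        dec_o = decompose(model, coils[1], lib, M=3)
        free = solve_design(no_comp(target=dec_t, gap=None, off_cutoffs={}), lib)
        gapped = solve_design(
            no_comp(target=dec_t, off_targets=[dec_o], gap=0.3), lib
        )
        if gapped.choice:
            assert gapped.S_target >= free.S_target - 1e-9

    def test_best_library_binder_bounds_the_design(self, design_world):
        coils, model, _ = design_world
        target, binder = coils[0], coils[1]
        lib = build_library([binder, coils[2]], prefilter=False)
        M = 3
        dec = decompose(model, target, lib, M=M)
        sol = solve_design(no_comp(target=dec, gap=None, off_cutoffs={}), lib)
        binder_score = model.predict(
            encode(binder.block_subcoil(1, M), target.block_subcoil(1, M))
        )
        assert sol.S_target <= binder_score + 1e-9


class TestCompositionConstraints:
    def _lib(self, seqs):
        coils = [assign_register(f"c{i}", s, "f") for i, s in enumerate(seqs)]
        return build_library(coils, prefilter=False)

    def test_his_at_d_fixed_outside_last_block(self, design_world):
        lib = self._lib(["QEKKLHE"])  # d = His
        prob = no_comp(target=None, his_d_last_only=True, library=lib)
        prob.target = type("D", (), {"M": 3})()
        rows, fixed = composition_constraints(prob)
        assert (1, 0) in fixed and (2, 0) in fixed and (3, 0) not in fixed

    def test_two_forced_met_d_is_infeasible(self, design_world):
        coils, model, _ = design_world
        lib = self._lib(["QEKKLME"])  # d = Met, the only entry
        dec = decompose(model, coils[0], lib, M=2)
        prob = no_comp(target=dec, gap=None, off_cutoffs={}, max_met_d=1, library=lib)
        sol = solve_design(prob, lib)
        assert not sol.choice  # needs Met at d in both blocks but only 1 allowed
        choice, _ = enumerate_designs(prob, lib)
        assert choice is None

    def test_polar_a_budget_enforced(self, design_world):
        coils, model, _ = design_world
        lib = self._lib(["QEKKLLE"])  # a = K is polar
        dec = decompose(model, coils[0], lib, M=3)
        prob = no_comp(target=dec, gap=None, off_cutoffs={}, max_polar_a=2, library=lib)
        sol = solve_design(prob, lib)
        assert not sol.choice

    def test_rare_pair_veto_matches_counting_oracle(self, design_world):
        coils, _, _ = design_world
        recs, seen = [], set()
        rng = np.random.default_rng(5)
        ids = [c.id for c in coils]
        for _ in range(40):
            i, j = rng.integers(0, len(ids), 2)
            pair = frozenset((ids[i], ids[j]))
            if pair in seen:
                continue
            seen.add(pair)
            recs.append(
                InteractionRecord(
                    idA=min(ids[i], ids[j]),
                    idB=max(ids[i], ids[j]),
                    kd_nM=float(rng.choice([50.0, 400.0, 5000.0])),
                )
            )
        ds = Dataset(coils={c.id: c for c in coils}, records=recs)
        is_rare = rare_core_pairs(ds, strong_cut=250.0, min_count=2)
        # oracle: count a/d pairs over strong records directly
        counts = {}
        for r in recs:
            if r.kd_nM >= 250.0:
                continue
            A, B = ds.coils[r.idA], ds.coils[r.idB]
            for k in range(1, min(A.n_blocks, B.n_blocks) + 1):
                for off, pos in ((2, "a"), (5, "d")):
                    p = tuple(sorted((A.block_seq(k)[off], B.block_seq(k)[off])))
                    counts[(pos, p)] = counts.get((pos, p), 0) + 1
        for (pos, p), c in counts.items():
            assert is_rare(pos, p[0], p[1]) == (c < 2)
        assert is_rare("a", "W", "W")  # never observed


class TestVerifySolution:
    def _solved(self, design_world, gap=0.3):
        coils, model, library = design_world
        lib = HeptadLibrary(entries=library.entries[:10])
        target, off = coils[0], coils[1]
        dec_t = decompose(model, target, lib, M=3)
        dec_o = decompose(model, off, lib, M=3)
        prob = no_comp(target=dec_t, off_targets=[dec_o], gap=gap)
        sol = solve_design(prob, lib)
        assert sol.choice
        return sol, model, prob, lib, {target.id: target, off.id: off}

    def test_valid_solution_passes(self, design_world):
        sol, model, prob, lib, partners = self._solved(design_world)
        report = verify_solution(sol, model, prob, lib, partners)
        assert report["ok"], report["violations"]

    def test_corrupted_heptad_is_flagged(self, design_world):
        sol, model, prob, lib, partners = self._solved(design_world)
        bad = type(sol)(
            choice=[(c + 1) % len(lib) for c in sol.choice],
            sequence=sol.sequence,
            S_target=sol.S_target,
            S_off=sol.S_off,
            status=sol.status,
            mip_gap=sol.mip_gap,
        )
        report = verify_solution(bad, model, prob, lib, partners)
        assert not report["ok"]

    def test_gap_shortfall_is_flagged(self, design_world):
        sol, model, prob, lib, partners = self._solved(design_world)
        achieved = min(sol.S_off.values()) - sol.S_target
        prob.gap = achieved + 0.1  # demand slightly more than achieved
        report = verify_solution(sol, model, prob, lib, partners)
        assert not report["ok"]
        assert any("gap shortfall" in v for v in report["violations"])
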