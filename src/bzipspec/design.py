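"""Heptad-assembly design of selective coiled-coil binders.

New binders are assembled from native 7-residue heptad modules (f,g,a,b,c,d,e
order).  Because the scoring model is a linear sum over residue contacts, the
score of an assembled design against a fixed partner decomposes exactly into
per-block terms ``s_i^j`` (library heptad j placed at design block i; every
contact whose design residues fall inside block i) and junction corrections
``c_{i,i+1}^{j,k}`` (contacts whose design residues span blocks i and i+1 —
the cross-block pair category d_i-a'_{i+1} as well as cross-block triplets).
The assembly that minimizes the target score subject to off-target score
floors, junction admissibility and composition rules is found by integer
linear programming (HiGHS branch and bound via scipy).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .features import FeatureKey, encode, enumerate_sites
from .registers import RegisteredCoil
from .semisvr import WeightModel

#: residues covering 85% of native occurrences at the core positions
A_ALPHABET = set("LNVIKART")
D_ALPHABET = set("LHVMI")
GE_ALPHABET = set("EKRQL")

POLAR_A = set("NKRETA")

# offsets inside an (f,g,a,b,c,d,e) block
OFF_F, OFF_G, OFF_A, OFF_B, OFF_C, OFF_D, OFF_E = range(7)


@dataclass(frozen=True)
class HeptadEntry:
    seq: str  # 7 residues, (f,g,a,b,c,d,e) order
    source: str
    n_terminal: bool

    def at(self, offset: int) -> str:
        return self.seq[offset]


@dataclass
class HeptadLibrary:
    entries: list[HeptadEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, j: int) -> HeptadEntry:
        return self.entries[j]


def build_library(
    coils,
    extra_sources=(),
    prefilter: bool = True,
) -> HeptadLibrary:
    """Extract unique f-anchored heptads from registered coils.

    The first full block of each source is flagged ``n_terminal`` (native
    N-terminal heptads are more polar and are restricted to the N-terminal
    design position).  With ``prefilter``, only heptads whose a and d
    residues come from the frequent native alphabets are retained.
    """
    if isinstance(coils, dict):
        coils = list(coils.values())
    coils = list(coils) + list(extra_sources)
    seen: dict[str, HeptadEntry] = {}
    for coil in coils:
        for k in range(1, coil.n_blocks + 1):
            seq = coil.block_seq(k)
            if prefilter and (seq[OFF_A] not in A_ALPHABET or seq[OFF_D] not in D_ALPHABET):
                continue
            if seq not in seen:
                seen[seq] = HeptadEntry(seq=seq, source=coil.id, n_terminal=(k == 1))
            elif k == 1 and not seen[seq].n_terminal:
                seen[seq] = HeptadEntry(seq=seq, source=seen[seq].source, n_terminal=True)
    return HeptadLibrary(entries=list(seen.values()))


def design_space_size(n_entries: int, n_blocks: int) -> int:
    """Number of distinct assemblies of ``n_blocks`` library heptads."""
    return n_entries**n_blocks


def basis_size(
    a_alphabet=A_ALPHABET, d_alphabet=D_ALPHABET, g_alphabet=GE_ALPHABET, e_alphabet=GE_ALPHABET
) -> int:
    """Size of the a/d/g/e combination basis the library is drawn from."""
    return len(a_alphabet) * len(d_alphabet) * len(g_alphabet) * len(e_alphabet)


# -- score decomposition ---------------------------------------------------------


@dataclass
class ScoreDecomposition:
    """Exact split of the dimer score into block and junction terms.

    ``s[i-1][j]`` scores library heptad j at design block i against the
    partner; ``c[i-1][j][k]`` corrects for contacts spanning design blocks
    i, i+1 occupied by heptads j, k.  For any assembly the sum of its s and c
    terms equals the full model score of the assembled sequence.
    """

    M: int
    s: np.ndarray  # (M, N)
    c: np.ndarray  # (M-1, N, N)
    partner_id: str


def assemble(library: HeptadLibrary, choice: list[int], design_id: str = "design") -> RegisteredCoil:
    """Concatenate chosen heptads into an f-phased registered coil."""
    seq = "".join(library[j].seq for j in choice)
    return RegisteredCoil(
        id=design_id, residues=seq, register=("fgabcde" * len(choice))
    )


def decompose(
    model: WeightModel,
    partner: RegisteredCoil,
    library: HeptadLibrary,
    M: int | None = None,
    anchor: int = 1,
) -> ScoreDecomposition:
    """Pre-compute block scores and junction corrections against a partner.

    The partner is scored over ``M`` blocks starting at its block ``anchor``
    (longer off-targets default to their first full block).  Contacts are
    enumerated once on a placeholder design chain; each contact's design-side
    residue indices determine whether it contributes to an s or a c term.
    """
    if M is None:
        M = partner.n_blocks - anchor + 1
    if partner.n_blocks - anchor + 1 < M:
        raise ValueError(
            f"partner {partner.id!r} has {partner.n_blocks} blocks; "
            f"cannot align {M} from block {anchor}"
        )
    part = partner.block_subcoil(anchor, M)  # always f-phased, exactly M blocks
    template = assemble(library, [0] * M, design_id="__template__")
    sites = enumerate_sites(template, part)

    N = len(library)
    entry_seqs = [e.seq for e in library.entries]
    s = np.zeros((M, N))
    c = np.zeros((max(M - 1, 0), N, N))
    for cat, st in sites:
        design_blocks = sorted({idx // 7 for chain, idx in st if chain == 0})
        if not design_blocks:
            continue
        if len(design_blocks) > 2 or (
            len(design_blocks) == 2 and design_blocks[1] - design_blocks[0] != 1
        ):
            raise AssertionError(
                f"contact {cat} spans non-adjacent design blocks {design_blocks}"
            )
        if len(design_blocks) == 1:
            b = design_blocks[0]
            for j in range(N):
                residues = tuple(
                    entry_seqs[j][idx % 7] if chain == 0 else part.residues[idx]
                    for chain, idx in st
                )
                wgt = model.w.get(FeatureKey(cat, residues), 0.0)
                if wgt:
                    s[b, j] += wgt
        else:
            b = design_blocks[0]
            # which offsets belong to which block decides how (j, k) fill in
            for j in range(N):
                for k in range(N):
                    residues = tuple(
                        (
                            entry_seqs[j][idx % 7]
                            if idx // 7 == b
                            else entry_seqs[k][idx % 7]
                        )
                        if chain == 0
                        else part.residues[idx]
                        for chain, idx in st
                    )
                    wgt = model.w.get(FeatureKey(cat, residues), 0.0)
                    if wgt:
                        c[b, j, k] += wgt
    # the intercept is assembly-independent; fold it into block 1 scores
    if model.intercept:
        s[0, :] += model.intercept
    return ScoreDecomposition(M=M, s=s, c=c, partner_id=partner.id)


def assembly_score(dec: ScoreDecomposition, choice: list[int]) -> float:
    total = sum(dec.s[i, j] for i, j in enumerate(choice))
    for i in range(dec.M - 1):
        total += dec.c[i, choice[i], choice[i + 1]]
    return float(total)


# -- junction admissibility ------------------------------------------------------


def junction_rules(library: HeptadLibrary, native_coils) -> set[tuple[int, int]]:
    """Allowed adjacencies (j, k): heptad j directly before heptad k.

    An adjacency is admissible when each of the three intra-chain residue
    pairs crossing the junction — (e of j, f of k), (d of j, g of k) and
    (e of j, a of k) — occurs at those relative positions in at least one
    native registered coil.
    """
    if isinstance(native_coils, dict):
        native_coils = list(native_coils.values())
    ef: set[tuple[str, str]] = set()
    dg: set[tuple[str, str]] = set()
    ea: set[tuple[str, str]] = set()
    for coil in native_coils:
        for k in range(1, coil.n_blocks):
            b1, b2 = coil.block_seq(k), coil.block_seq(k + 1)
            ef.add((b1[OFF_E], b2[OFF_F]))
            dg.add((b1[OFF_D], b2[OFF_G]))
            ea.add((b1[OFF_E], b2[OFF_A]))
    allowed = set()
    for j, ej in enumerate(library.entries):
        for k, ek in enumerate(library.entries):
            if (
                (ej.at(OFF_E), ek.at(OFF_F)) in ef
                and (ej.at(OFF_D), ek.at(OFF_G)) in dg
                and (ej.at(OFF_E), ek.at(OFF_A)) in ea
            ):
                allowed.add((j, k))
    return allowed


# -- composition constraints -----------------------------------------------------


def rare_core_pairs(dataset, strong_cut: float = 250.0, min_count: int = 2):
    """Count a-a' and d-d' residue pairs among strong binders; return the set
    of (position, pair) seen fewer than ``min_count`` times.

    Used to veto design heptads whose core residue would form a pair with the
    target that the training data barely supports.
    """
    from .features import FeatureKey

    counts: dict[tuple[str, tuple[str, str]], int] = {}
    for rec in dataset.records:
        if rec.kd_nM >= strong_cut:
            continue
        fv = encode(
            dataset.coils[rec.idA], dataset.coils[rec.idB], categories=("a-a'", "d-d'")
        )
        for key, x in fv.items():
            pos = "a" if key.category == "a-a'" else "d"
            counts[(pos, key.residues)] = counts.get((pos, key.residues), 0) + x

    def is_rare(pos: str, r1: str, r2: str) -> bool:
        return counts.get((pos, tuple(sorted((r1, r2)))), 0) < min_count

    return is_rare


@dataclass
class DesignProblem:
    """An ILP instance: choose one library heptad per design block.

    ``gap`` switches between relative mode (every off-target score must
    exceed the target score by ``gap`` log10 units; the default 2.0 is a
    >100-fold predicted Kd margin) and absolute mode (``off_cutoffs`` gives a
    floor per off-target).
    """

    target: ScoreDecomposition
    off_targets: list[ScoreDecomposition] = field(default_factory=list)
    allowed_adjacency: set[tuple[int, int]] | None = None
    gap: float | None = 2.0
    off_cutoffs: dict[str, float] | None = None
    # composition rules
    library: HeptadLibrary | None = None
    max_met_d: int | None = 1
    max_polar_a: int | None = 4
    his_d_last_only: bool = True
    glu_a_first_only: bool = True
    asn_a_nonterminal_only: bool = True
    n_terminal_entries_first_only: bool = True
    forbidden_at_block: set[tuple[int, int]] = field(default_factory=set)  # (i, j) 1-based i


@dataclass
class DesignSolution:
    choice: list[int]
    sequence: str
    S_target: float
    S_off: dict[str, float]
    status: str
    mip_gap: float


def forbidden_core_pairs_vetoes(
    problem_target: RegisteredCoil,
    library: HeptadLibrary,
    M: int,
    anchor: int = 1,
    coupling_energies: dict[tuple[str, tuple[str, str]], float] | None = None,
    is_rare=None,
) -> set[tuple[int, int]]:
    """Per-block vetoes (i, j) for heptads whose a/d residue forms a
    destabilizing (> 1 kcal/mol coupling energy) or rarely observed core pair
    with the target's opposing residue."""
    vetoes: set[tuple[int, int]] = set()
    for i in range(1, M + 1):
        tgt_block = problem_target.block_seq(anchor + i - 1)
        for j, entry in enumerate(library.entries):
            for pos, off in (("a", OFF_A), ("d", OFF_D)):
                pair = tuple(sorted((entry.at(off), tgt_block[off])))
                if coupling_energies is not None:
                    if coupling_energies.get((pos, pair), 0.0) > 1.0:
                        vetoes.add((i, j))
                if is_rare is not None and is_rare(pos, pair[0], pair[1]):
                    vetoes.add((i, j))
    return vetoes


def composition_constraints(problem: DesignProblem) -> tuple[list[tuple], set[tuple[int, int]]]:
    """Expand the knowledge-based rules into cardinality rows and x-fixings.

    Returns (rows, fixed_zero) where each row is (coefficient dict over
    (i, j) with i 1-based, upper bound) and ``fixed_zero`` lists variables
    forced to zero.
    """
    lib = problem.library
    if lib is None:
        return [], set(problem.forbidden_at_block)
    M = problem.target.M
    fixed: set[tuple[int, int]] = set(problem.forbidden_at_block)
    rows: list[tuple] = []
    for j, entry in enumerate(lib.entries):
        a_res, d_res = entry.at(OFF_A), entry.at(OFF_D)
        for i in range(1, M + 1):
            if problem.his_d_last_only and d_res == "H" and i != M:
                fixed.add((i, j))
            if problem.glu_a_first_only and a_res == "E" and i != 1:
                fixed.add((i, j))
            if problem.asn_a_nonterminal_only and a_res == "N" and i in (1, M):
                fixed.add((i, j))
            if problem.n_terminal_entries_first_only and entry.n_terminal and i != 1:
                fixed.add((i, j))
    if problem.max_met_d is not None:
        coeffs = {
            (i, j): 1.0
            for i in range(1, M + 1)
            for j, e in enumerate(lib.entries)
            if e.at(OFF_D) == "M"
        }
        if coeffs:
            rows.append((coeffs, float(problem.max_met_d)))
    if problem.max_polar_a is not None:
        coeffs = {
            (i, j): 1.0
            for i in range(1, M + 1)
            for j, e in enumerate(lib.entries)
            if e.at(OFF_A) in POLAR_A
        }
        if coeffs:
            rows.append((coeffs, float(problem.max_polar_a)))
    return rows, fixed


# -- the ILP ---------------------------------------------------------------------


def solve_design(
    problem: DesignProblem,
    library: HeptadLibrary,
    time_limit: float | None = None,
    design_id: str = "design",
) -> DesignSolution:
    """Minimize the target score over heptad assemblies subject to all
    constraints; returns the proven optimum (or best incumbent with its gap).
    """
    tgt = problem.target
    M, N = tgt.M, len(library)
    offs = problem.off_targets
    adj = problem.allowed_adjacency
    if adj is None:
        adj = {(j, k) for j in range(N) for k in range(N)}

    if problem.library is None:
        problem.library = library
    comp_rows, fixed_zero = composition_constraints(problem)

    # variable layout: x (M*N), then z per junction for allowed (j, k)
    nx = M * N

    def xi(i: int, j: int) -> int:  # i 1-based
        return (i - 1) * N + j

    z_index: dict[tuple[int, int, int], int] = {}
    pos = nx
    for i in range(1, M):
        for (j, k) in sorted(adj):
            z_index[(i, j, k)] = pos
            pos += 1
    nvar = pos

    cvec = np.zeros(nvar)
    for i in range(1, M + 1):
        for j in range(N):
            cvec[xi(i, j)] = tgt.s[i - 1, j]
    for (i, j, k), v in z_index.items():
        cvec[v] = tgt.c[i - 1, j, k]

    rows_A, rows_lb, rows_ub = [], [], []

    def add_row(coeffs: dict[int, float], lb: float, ub: float) -> None:
        rows_A.append(coeffs)
        rows_lb.append(lb)
        rows_ub.append(ub)

    for i in range(1, M + 1):
        add_row({xi(i, j): 1.0 for j in range(N)}, 1.0, 1.0)
    for i in range(1, M):
        for k in range(N):
            coeffs = {z_index[(i, j, k)]: 1.0 for j in range(N) if (j, k) in adj}
            coeffs[xi(i + 1, k)] = coeffs.get(xi(i + 1, k), 0.0) - 1.0
            add_row(coeffs, 0.0, 0.0)
        for j in range(N):
            coeffs = {z_index[(i, j, k)]: 1.0 for k in range(N) if (j, k) in adj}
            coeffs[xi(i, j)] = coeffs.get(xi(i, j), 0.0) - 1.0
            add_row(coeffs, 0.0, 0.0)

    for dec in offs:
        if dec.M != M:
            raise ValueError(
                f"off-target {dec.partner_id!r} decomposed over {dec.M} blocks, "
                f"target over {M}"
            )
        coeffs: dict[int, float] = {}
        for i in range(1, M + 1):
            for j in range(N):
                coeffs[xi(i, j)] = coeffs.get(xi(i, j), 0.0) + dec.s[i - 1, j]
        for (i, j, k), v in z_index.items():
            coeffs[v] = coeffs.get(v, 0.0) + dec.c[i - 1, j, k]
        if problem.gap is not None:
            # S_off - S_target >= gap
            for i in range(1, M + 1):
                for j in range(N):
                    coeffs[xi(i, j)] -= tgt.s[i - 1, j]
            for (i, j, k), v in z_index.items():
                coeffs[v] -= tgt.c[i - 1, j, k]
            add_row(coeffs, problem.gap, np.inf)
        else:
            cutoff = (problem.off_cutoffs or {}).get(dec.partner_id)
            if cutoff is None:
                raise ValueError(f"no cutoff given for off-target {dec.partner_id!r}")
            add_row(coeffs, cutoff, np.inf)

    for coeffs_ij, ub in comp_rows:
        add_row({xi(i, j): v for (i, j), v in coeffs_ij.items()}, -np.inf, ub)

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    for (i, j) in fixed_zero:
        if 1 <= i <= M:
            ub[xi(i, j)] = 0.0

    data, ri, ci = [], [], []
    for r, coeffs in enumerate(rows_A):
        for v, coef in coeffs.items():
            ri.append(r)
            ci.append(v)
            data.append(coef)
    A = sp.csr_matrix((data, (ri, ci)), shape=(len(rows_A), nvar))

    options = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = time_limit
    # z variables relax to continuous: for any integral x their transportation
    # constraints admit exactly one solution, which is 0/1
    integrality = np.zeros(nvar)
    integrality[:nx] = 1
    res = milp(
        c=cvec,
        constraints=LinearConstraint(A, np.array(rows_lb), np.array(rows_ub)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=options,
    )
    if res.x is None:
        return DesignSolution(
            choice=[], sequence="", S_target=math.nan, S_off={}, status=res.message, mip_gap=math.nan
        )
    xsol = res.x[:nx].reshape(M, N)
    choice = [int(np.argmax(xsol[i])) for i in range(M)]
    coil = assemble(library, choice, design_id=design_id)
    s_target = assembly_score(tgt, choice)
    s_off = {dec.partner_id: assembly_score(dec, choice) for dec in offs}
    return DesignSolution(
        choice=choice,
        sequence=coil.residues,
        S_target=s_target,
        S_off=s_off,
        status="optimal" if res.status == 0 else res.message,
        mip_gap=float(getattr(res, "mip_gap", 0.0) or 0.0),
    )


def enumerate_designs(
    problem: DesignProblem, library: HeptadLibrary
) -> tuple[list[int] | None, float]:
    """Brute-force search over all assemblies (tiny instances only)."""
    tgt = problem.target
    M, N = tgt.M, len(library)
    adj = problem.allowed_adjacency
    if problem.library is None:
        problem.library = library
    comp_rows, fixed_zero = composition_constraints(problem)
    best: tuple[float, list[int] | None] = (math.inf, None)
    for choice in itertools.product(range(N), repeat=M):
        if any((i + 1, j) in fixed_zero for i, j in enumerate(choice)):
            continue
        if adj is not None and any(
            (choice[i], choice[i + 1]) not in adj for i in range(M - 1)
        ):
            continue
        ok = True
        for coeffs, ubound in comp_rows:
            if sum(coeffs.get((i + 1, j), 0.0) for i, j in enumerate(choice)) > ubound:
                ok = False
                break
        if not ok:
            continue
        s_t = assembly_score(tgt, list(choice))
        feasible = True
        for dec in problem.off_targets:
            s_o = assembly_score(dec, list(choice))
            if problem.gap is not None:
                if s_o - s_t < problem.gap:
                    feasible = False
                    break
            else:
                if s_o < (problem.off_cutoffs or {}).get(dec.partner_id, -math.inf):
                    feasible = False
                    break
        if feasible and s_t < best[0]:
            best = (s_t, list(choice))
    return best[1], best[0]


def verify_solution(
    solution: DesignSolution,
    model: WeightModel,
    problem: DesignProblem,
    library: HeptadLibrary,
    partners: dict[str, RegisteredCoil],
    anchor: dict[str, int] | None = None,
    tol: float = 1e-9,
) -> dict:
    """Re-score the assembled design from scratch and check every guarantee.

    The design is re-encoded against the target and every off-target with the
    feature module (no decomposition), the scores are compared to the ILP's,
    and gap/cutoff and composition rules are re-checked on the final
    sequence.
    """
    report: dict = {"ok": True, "violations": []}
    coil = assemble(library, solution.choice)
    anchor = anchor or {}

    def full_score(pid: str, dec: ScoreDecomposition) -> float:
        part = partners[pid]
        sub = part.block_subcoil(anchor.get(pid, 1), dec.M)
        return model.predict(encode(coil, sub))

    s_t = full_score(problem.target.partner_id, problem.target)
    if abs(s_t - solution.S_target) > tol:
        report["ok"] = False
        report["violations"].append(
            f"target score mismatch: recomputed {s_t!r} vs ILP {solution.S_target!r}"
        )
    for dec in problem.off_targets:
        s_o = full_score(dec.partner_id, dec)
        if abs(s_o - solution.S_off[dec.partner_id]) > tol:
            report["ok"] = False
            report["violations"].append(f"off-target {dec.partner_id} score mismatch")
        if problem.gap is not None and s_o - s_t < problem.gap - tol:
            report["ok"] = False
            report["violations"].append(
                f"specificity gap shortfall for {dec.partner_id}: {s_o - s_t:.3f} < {problem.gap}"
            )
    # composition rules on the final sequence
    lib_entries = [library[j] for j in solution.choice]
    M = len(lib_entries)
    if problem.max_met_d is not None:
        n_met = sum(e.at(OFF_D) == "M" for e in lib_entries)
        if n_met > problem.max_met_d:
            report["ok"] = False
            report["violations"].append(f"{n_met} Met at d exceeds {problem.max_met_d}")
    if problem.max_polar_a is not None:
        n_polar = sum(e.at(OFF_A) in POLAR_A for e in lib_entries)
        if n_polar > problem.max_polar_a:
            report["ok"] = False
            report["violations"].append(f"{n_polar} polar a residues exceeds {problem.max_polar_a}")
    for i, e in enumerate(lib_entries, start=1):
        if problem.his_d_last_only and e.at(OFF_D) == "H" and i != M:
            report["ok"] = False
            report["violations"].append(f"His at d in non-terminal block {i}")
        if problem.glu_a_first_only and e.at(OFF_A) == "E" and i != 1:
            report["ok"] = False
            report["violations"].append(f"Glu at a outside first block ({i})")
        if problem.asn_a_nonterminal_only and e.at(OFF_A) == "N" and i in (1, M):
            report["ok"] = False
            report["violations"].append(f"Asn at a in terminal block {i}")
    report["S_target_recomputed"] = s_t
    return report


def family_filter(
    target: RegisteredCoil, candidates: list[RegisteredCoil], max_identity: float = 0.60
) -> list[RegisteredCoil]:
    """Drop candidate off-targets in the target's own family (high core identity)."""
    from .validation import core_identity

    return [c for c in candidates if core_identity(target, c) <= max_identity]
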