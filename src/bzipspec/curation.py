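"""Dataset curation filters and binder-class labelling.

Three filters remove measurements whose sequence-to-structure alignment or
affinity value is unreliable:

1. asparagine mismatches — an Asn at an ``a`` position facing Val/Leu/Ile is
   strongly destabilizing, and such pairs may not dimerize in the canonical
   register; records with a mismatch in a non-terminal heptad are dropped;
2. PSSM outliers — proteins with uncharacteristic residues at a, d, e, g
   positions (scored by ``s_i(aa) = -log(p_i(aa) / p(aa))``) are dropped
   together with every interaction they participate in;
3. variant conflicts — records whose coiled-coil regions are identical for
   both partners but whose Kd values disagree are contradictory and dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data import Dataset, InteractionRecord
from .registers import AMINO_ACIDS, CORE_POSITIONS, RegisteredCoil

ASN_PARTNERS = set("VLI")


def _aligned_blocks(a: RegisteredCoil, b: RegisteredCoil) -> list[int]:
    """Block indices (1-based) compared between two coils: paired by index
    over the overlap, all coils assumed on a common register frame."""
    return list(range(1, min(a.n_blocks, b.n_blocks) + 1))


def filter_asn_mismatch(dataset: Dataset) -> tuple[Dataset, list[frozenset[str]]]:
    """Drop records with an Asn/{V,L,I} mismatch at a non-terminal ``a`` site.

    The first and last aligned blocks are exempt: terminal Asn mismatches are
    far less destabilizing and do not imply a register shift.
    """
    kept, excluded = [], []
    for rec in dataset.records:
        A, B = dataset.coils[rec.idA], dataset.coils[rec.idB]
        blocks = _aligned_blocks(A, B)
        mismatch = False
        for k in blocks:
            if k == blocks[0] or k == blocks[-1]:
                continue
            ra = A.block_seq(k)[2]  # 'a' sits at offset 2 of an f-anchored block
            rb = B.block_seq(k)[2]
            if (ra == "N" and rb in ASN_PARTNERS) or (rb == "N" and ra in ASN_PARTNERS):
                mismatch = True
                break
        (excluded if mismatch else kept).append(rec.pair if mismatch else rec)
    return dataset.subset([r for r in kept]), excluded


@dataclass
class PssmTable:
    """Position-specific scores over a, d, e, g positions.

    ``scores[pos][aa] = -log(p_pos(aa) / p(aa))`` with add-one smoothing, so
    frequent residues at a position score low and the score is exactly zero
    when the positional and background probabilities agree.
    """

    p_pos: dict[str, dict[str, float]]
    p_bg: dict[str, float]
    scores: dict[str, dict[str, float]]

    def protein_score(self, coil: RegisteredCoil, normalize: bool = True) -> float:
        total, count = 0.0, 0
        for res, lab in zip(coil.residues, coil.register):
            if lab in CORE_POSITIONS:
                total += self.scores[lab][res]
                count += 1
        if count == 0:
            return 0.0
        return total / count if normalize else total


def build_pssm(coils: dict[str, RegisteredCoil] | list[RegisteredCoil]) -> PssmTable:
    if isinstance(coils, dict):
        coils = list(coils.values())
    pos_counts = {p: {aa: 1 for aa in AMINO_ACIDS} for p in CORE_POSITIONS}  # add-one
    bg_counts = {aa: 1 for aa in AMINO_ACIDS}
    for coil in coils:
        for res, lab in zip(coil.residues, coil.register):
            bg_counts[res] += 1
            if lab in CORE_POSITIONS:
                pos_counts[lab][res] += 1
    bg_total = sum(bg_counts.values())
    p_bg = {aa: c / bg_total for aa, c in bg_counts.items()}
    p_pos, scores = {}, {}
    for p in CORE_POSITIONS:
        total = sum(pos_counts[p].values())
        p_pos[p] = {aa: c / total for aa, c in pos_counts[p].items()}
        scores[p] = {aa: -math.log(p_pos[p][aa] / p_bg[aa]) for aa in AMINO_ACIDS}
    return PssmTable(p_pos=p_pos, p_bg=p_bg, scores=scores)


def pssm_outlier_filter(
    dataset: Dataset, fraction: float = 0.10, normalize: bool = True
) -> tuple[Dataset, list[str]]:
    """Drop the top ``fraction`` of proteins by PSSM score and their records.

    Exactly ``ceil(fraction * n_proteins)`` proteins are removed; ties are
    broken by stable (score desc, id asc) ordering.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = dataset.protein_ids()
    pssm = build_pssm([dataset.coils[i] for i in ids])
    scored = sorted(
        ids, key=lambda i: (-pssm.protein_score(dataset.coils[i], normalize), i)
    )
    n_drop = math.ceil(fraction * len(ids))
    dropped = set(scored[:n_drop])
    kept = [r for r in dataset.records if not ({r.idA, r.idB} & dropped)]
    return dataset.subset(kept), sorted(dropped)


def _cc_region(coil: RegisteredCoil) -> str:
    """The registered coiled-coil region: residues covered by full blocks."""
    if not coil.blocks:
        return coil.residues
    s, e = coil.blocks[0], coil.blocks[-1] + 7
    return coil.residues[s:e]


def filter_variant_conflicts(dataset: Dataset) -> tuple[Dataset, list[frozenset[str]]]:
    """Resolve records that share identical coiled-coil regions.

    Records whose both partners have identical region sequences describe the
    same interaction motif.  If their Kd values agree the duplicates collapse
    to one record; if they disagree the measurements are contradictory and
    all of them are removed.
    """
    groups: dict[frozenset[str], list[InteractionRecord]] = {}
    for rec in dataset.records:
        key = frozenset(
            (_cc_region(dataset.coils[rec.idA]), _cc_region(dataset.coils[rec.idB]))
        )
        groups.setdefault(key, []).append(rec)
    kept, excluded = [], []
    for recs in groups.values():
        kds = {r.kd_nM for r in recs}
        if len(recs) == 1 or len(kds) == 1:
            kept.append(recs[0])
            excluded.extend(r.pair for r in recs[1:])
        else:
            excluded.extend(r.pair for r in recs)
    order = {r.pair: i for i, r in enumerate(dataset.records)}
    kept.sort(key=lambda r: order[r.pair])
    return dataset.subset(kept), excluded


def curate(
    dataset: Dataset,
    asn_filter: bool = True,
    pssm_fraction: float | None = 0.10,
    variant_filter: bool = True,
) -> tuple[Dataset, dict]:
    """Full curation pipeline; returns the curated dataset and an exclusion log."""
    log: dict = {}
    if asn_filter:
        dataset, excl = filter_asn_mismatch(dataset)
        log["asn_mismatch"] = excl
    if pssm_fraction:
        dataset, excl = pssm_outlier_filter(dataset, pssm_fraction)
        log["pssm_outliers"] = excl
    if variant_filter:
        dataset, excl = filter_variant_conflicts(dataset)
        log["variant_conflicts"] = excl
    return dataset, log


def label_classes(
    dataset: Dataset,
    strong_cut: float = 250.0,
    weak_cut: float = 5000.0,
    binder_lo: float = 50.0,
) -> list[dict]:
    """Two labellings per record: the ROC classes and the stratification bins.

    * ``auc_class``: 'strong' (Kd < strong_cut), 'weak_non' (Kd >= weak_cut),
      or 'intermediate' (excluded from the AUC test);
    * ``stratum``: '<50', '50-5000', or '>=5000' nM, used to balance folds.
    """
    out = []
    for rec in dataset.records:
        kd = rec.kd_nM
        if kd < strong_cut:
            auc_class = "strong"
        elif kd >= weak_cut:
            auc_class = "weak_non"
        else:
            auc_class = "intermediate"
        if kd < binder_lo:
            stratum = "<50"
        elif kd < weak_cut:
            stratum = "50-5000"
        else:
            stratum = ">=5000"
        out.append(
            {"idA": rec.idA, "idB": rec.idB, "auc_class": auc_class, "stratum": stratum}
        )
    return out
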