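"""Pair/triplet interface features for parallel coiled-coil dimers.

A dimer is represented as counts of discrete residue contacts at the a, d, e
and g interface positions.  Eight pair categories and ten triplet categories
are defined in the canonical a-frame; a category element is (chain, position,
heptad offset) with chain 0 the unprimed chain and chain 1 the primed
(opposing) chain.  Four pair categories are symmetric in chain identity and
their residue keys are stored in lexicographic order; triplets are never
symmetrized.

Contacts are physical: every distinct set of residue sites forming a category
instance is counted once.  For aa' and dd' the two chain-role assignments
name the same pair of sites, so a heptad yields one contact; for all other
categories the two roles name distinct site sets and a heptad yields two
(which coincide in residue content for homodimers).  An optional
``single_role`` mode counts only the (A unprimed, B primed) role.
"""

from __future__ import annotations

from dataclasses import dataclass

from .registers import AMINO_ACIDS, RegisteredCoil

# (chain, position, heptad offset); chain 0 = unprimed, 1 = primed.
CATEGORIES: dict[str, dict] = {
    # pairs
    "a-a'": {"elements": ((0, "a", 0), (1, "a", 0)), "symmetric": True},
    "d-d'": {"elements": ((0, "d", 0), (1, "d", 0)), "symmetric": True},
    "g-e'+1": {"elements": ((0, "g", 0), (1, "e", 1)), "symmetric": True},
    "e-g'": {"elements": ((0, "e", 0), (1, "g", 0)), "symmetric": True},
    "a-d'": {"elements": ((0, "a", 0), (1, "d", 0)), "symmetric": False},
    "d-a'+1": {"elements": ((0, "d", 0), (1, "a", 1)), "symmetric": False},
    "d-e'": {"elements": ((0, "d", 0), (1, "e", 0)), "symmetric": False},
    "g-a'+1": {"elements": ((0, "g", 0), (1, "a", 1)), "symmetric": False},
    # triplets
    "a-d-a'": {"elements": ((0, "a", 0), (0, "d", 0), (1, "a", 0)), "symmetric": False},
    "d-a+1-d'": {"elements": ((0, "d", 0), (0, "a", 1), (1, "d", 0)), "symmetric": False},
    "g-d+1-e'+1": {"elements": ((0, "g", 0), (0, "d", 1), (1, "e", 1)), "symmetric": False},
    "g-a'+1-e'+1": {"elements": ((0, "g", 0), (1, "a", 1), (1, "e", 1)), "symmetric": False},
    "e-d'-g'": {"elements": ((0, "e", 0), (1, "d", 0), (1, "g", 0)), "symmetric": False},
    "e-a+1-g'": {"elements": ((0, "e", 0), (0, "a", 1), (1, "g", 0)), "symmetric": False},
    "a-g'-1-d'": {"elements": ((0, "a", 0), (1, "g", -1), (1, "d", 0)), "symmetric": False},
    "a-e-d'": {"elements": ((0, "a", 0), (0, "e", 0), (1, "d", 0)), "symmetric": False},
    "d-e'-a'+1": {"elements": ((0, "d", 0), (1, "e", 0), (1, "a", 1)), "symmetric": False},
    "d-g-a'+1": {"elements": ((0, "d", 0), (0, "g", 0), (1, "a", 1)), "symmetric": False},
}

PAIR_CATEGORIES = tuple(k for k, v in CATEGORIES.items() if len(v["elements"]) == 2)
TRIPLET_CATEGORIES = tuple(k for k, v in CATEGORIES.items() if len(v["elements"]) == 3)

#: the simplified three-category model (core layers plus the classic g-e' salt bridge)
BASIC_PAIR_CATEGORIES = ("a-a'", "d-d'", "g-e'+1")


@dataclass(frozen=True)
class FeatureKey:
    """One scored residue combination: a category plus an ordered residue tuple."""

    category: str
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        spec = CATEGORIES[self.category]
        if len(self.residues) != len(spec["elements"]):
            raise ValueError(
                f"category {self.category!r} takes {len(spec['elements'])} residues"
            )
        if spec["symmetric"]:
            object.__setattr__(self, "residues", tuple(sorted(self.residues)))

    def __str__(self) -> str:
        return f"{self.category}:{'-'.join(self.residues)}"

    @property
    def is_pair(self) -> bool:
        return len(self.residues) == 2

    @classmethod
    def parse(cls, token: str) -> "FeatureKey":
        cat, _, res = token.rpartition(":")
        return cls(category=cat, residues=tuple(res.split("-")))


FeatureVector = dict[FeatureKey, int]


def feature_space_size() -> dict[str, int]:
    """Number of possible residue combinations per category, plus the total."""
    n_aa = len(AMINO_ACIDS)
    sizes: dict[str, int] = {}
    for cat, spec in CATEGORIES.items():
        k = len(spec["elements"])
        if k == 2 and spec["symmetric"]:
            sizes[cat] = n_aa * (n_aa + 1) // 2
        else:
            sizes[cat] = n_aa**k
    sizes["total"] = sum(sizes[c] for c in CATEGORIES)
    return sizes


# -- contact enumeration -------------------------------------------------------


def enumerate_sites(
    coilA: RegisteredCoil,
    coilB: RegisteredCoil,
    categories: tuple[str, ...] | None = None,
    single_role: bool = False,
) -> list[tuple[str, tuple[tuple[int, int], ...]]]:
    """List every physical contact between two register-aligned coils.

    Chains are aligned by their a-frame heptad coordinates (heptad ``i`` of A
    faces heptad ``i`` of B).  Returns ``(category, sites)`` tuples where
    ``sites`` holds (chain, residue index) pairs ordered as the category's
    elements for the role in which the contact was first generated; the set
    of sites identifies the contact, so role-coincident contacts (aa', dd')
    appear once.  Cross-heptad contacts are emitted only when every heptad
    index they touch exists in both chains.
    """
    cats = categories or tuple(CATEGORIES)
    coords = (coilA.coord_index(), coilB.coord_index())
    loA, hiA = coilA.heptad_range()
    loB, hiB = coilB.heptad_range()
    lo, hi = max(loA, loB), min(hiA, hiB)

    def heptad_exists(h: int) -> bool:
        return loA <= h <= hiA and loB <= h <= hiB

    out: list[tuple[str, tuple[tuple[int, int], ...]]] = []
    seen: set[tuple[str, frozenset[tuple[int, int]]]] = set()
    roles = ((0, 1),) if single_role else ((0, 1), (1, 0))
    for i in range(lo - 1, hi + 2):  # pad by one: offsets reach i +/- 1
        for cat in cats:
            elements = CATEGORIES[cat]["elements"]
            for role in roles:
                sites = []
                ok = True
                for chain, pos, off in elements:
                    if not heptad_exists(i + off):
                        ok = False
                        break
                    phys = role[chain]
                    idx = coords[phys].get((i + off, pos))
                    if idx is None:
                        ok = False
                        break
                    sites.append((phys, idx))
                if not ok:
                    continue
                ident = (cat, frozenset(sites))
                if ident in seen:
                    continue
                seen.add(ident)
                out.append((cat, tuple(sites)))
    return out


def _key_for(cat: str, sites, seqs) -> FeatureKey:
    return FeatureKey(cat, tuple(seqs[chain][idx] for chain, idx in sites))


def encode(
    coilA: RegisteredCoil,
    coilB: RegisteredCoil,
    categories: tuple[str, ...] | None = None,
    single_role: bool = False,
) -> FeatureVector:
    """Sparse contact counts x for the dimer {coilA, coilB} (order-free)."""
    sites = enumerate_sites(coilA, coilB, categories=categories, single_role=single_role)
    if not sites:
        raise ValueError(
            f"coils {coilA.id!r} and {coilB.id!r} have no register overlap"
        )
    seqs = (coilA.residues, coilB.residues)
    counts: FeatureVector = {}
    for cat, st in sites:
        key = _key_for(cat, st, seqs)
        counts[key] = counts.get(key, 0) + 1
    return counts


def jaccard_distance(u: FeatureVector, v: FeatureVector) -> float:
    """Fraction of non-zero features that differ between two dimers."""
    su, sv = set(u), set(v)
    union = su | sv
    if not union:
        return 0.0
    return len(su ^ sv) / len(union)


def observed_features(
    dataset, categories: tuple[str, ...] | None = None, single_role: bool = False
) -> tuple[int, int, set[FeatureKey]]:
    """Distinct feature keys seen at least once across a dataset's records."""
    keys: set[FeatureKey] = set()
    for rec in dataset.records:
        fv = encode(
            dataset.coils[rec.idA],
            dataset.coils[rec.idB],
            categories=categories,
            single_role=single_role,
        )
        keys.update(fv)
    n_pairs = sum(k.is_pair for k in keys)
    return n_pairs, len(keys) - n_pairs, keys


class DimerFeaturizer:
    """Transformer from interaction records to a sparse count matrix.

    Follows the scikit-learn transformer protocol: ``fit`` learns the feature
    vocabulary (keys observed in the training dimers), ``transform`` maps
    records to a ``scipy.sparse.csr_matrix`` over that vocabulary.
    """

    def __init__(
        self,
        categories: tuple[str, ...] | None = None,
        single_role: bool = False,
    ):
        self.categories = categories
        self.single_role = single_role

    def get_params(self, deep: bool = True) -> dict:
        return {"categories": self.categories, "single_role": self.single_role}

    def set_params(self, **params) -> "DimerFeaturizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _encode_all(self, dataset, records) -> list[FeatureVector]:
        return [
            encode(
                dataset.coils[r.idA],
                dataset.coils[r.idB],
                categories=self.categories,
                single_role=self.single_role,
            )
            for r in records
        ]

    def fit(self, dataset, records=None) -> "DimerFeaturizer":
        records = dataset.records if records is None else records
        keys: set[FeatureKey] = set()
        for fv in self._encode_all(dataset, records):
            keys.update(fv)
        self.feature_keys_ = sorted(keys, key=str)
        self.key_index_ = {k: i for i, k in enumerate(self.feature_keys_)}
        return self

    def transform(self, dataset, records=None):
        import scipy.sparse as sp

        if not hasattr(self, "key_index_"):
            raise RuntimeError("DimerFeaturizer is not fitted")
        records = dataset.records if records is None else records
        rows, cols, vals = [], [], []
        for r, fv in enumerate(self._encode_all(dataset, records)):
            for key, count in fv.items():
                j = self.key_index_.get(key)
                if j is not None:
                    rows.append(r)
                    cols.append(j)
                    vals.append(count)
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(records), len(self.feature_keys_))
        )

    def fit_transform(self, dataset, records=None):
        return self.fit(dataset, records).transform(dataset, records)
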