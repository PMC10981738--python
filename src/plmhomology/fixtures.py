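"""Synthetic datasets with the statistical structure remote-homology search
assumes.

The generator plants a SCOP-style hierarchy (fold > superfamily > family),
and derives every modality from it:

* **Sequences** descend from a random fold-ancestor sequence by substitution
  mutations accumulated along the hierarchy, so within-fold pairs keep
  detectable sequence similarity while cross-fold pairs are unrelated.
* **Pooled embeddings** are nested Gaussian perturbations of a fold centroid
  (fold → superfamily → family → protein), mimicking how language-model
  embeddings cluster by structure.
* **Per-residue embeddings** come from the context-free mock encoder
  (one-hot per residue plus jitter), so alignment scores track sequence
  similarity.
* **Domain annotations** give each protein its family's Pfam accession,
  mapped to one clan per fold; a fraction of proteins additionally carry a
  "promiscuous" domain from a small set of big clans with power-law weights,
  reproducing the long-tailed clan-cluster distribution of real datasets
  (where a handful of big clusters dominate the pre-filtered pair count).
  A small fraction of proteins carries no domain at all, exercising the
  retain-all fallback.
* **TM-score labels** come from a planted bilinear form of the pooled
  embeddings plus Gaussian noise, so same-fold pairs score high (> 0.5) and
  cross-fold pairs low — and so the bilinear trainer has a recoverable
  ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncoderSpec, MockEncoder, pool
from .records import (
    AMINO_ACIDS,
    ClanMap,
    DomainAnnotation,
    FoldLabel,
    LabeledPair,
    ProteinRecord,
)
from .similarity import BilinearModel


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the planted-hierarchy generator; the seed fixes every draw."""

    n_folds: int = 5
    superfamilies_per_fold: int = 2
    families_per_superfamily: int = 2
    proteins_per_family: int = 5
    seq_length: tuple[int, int] = (50, 80)
    dim: int = 32
    sigma_emb: float = 0.10  # per-coordinate protein-level embedding noise
    sigma_sf: float = 0.15  # superfamily centroid offset scale
    sigma_family: float = 0.10  # family centroid offset scale
    sigma_residue: float = 0.05  # per-residue one-hot jitter
    sigma_tm: float = 0.02  # label noise
    tm_same_fold: float = 0.8  # planted same-fold TM level
    mutation_rate: float = 0.1  # per-branch substitution rate
    p_no_domain: float = 0.05
    p_extra_domain: float = 0.3
    n_big_clans: int = 2
    tail_exponent: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_folds,
            self.superfamilies_per_fold,
            self.families_per_superfamily,
            self.proteins_per_family,
            self.dim,
            self.n_big_clans,
        ) < 1:
            raise ValueError("hierarchy counts and dim must be >= 1")
        if self.seq_length[0] < 1 or self.seq_length[1] < self.seq_length[0]:
            raise ValueError("invalid seq_length range")

    @property
    def n_proteins(self) -> int:
        return (
            self.n_folds
            * self.superfamilies_per_fold
            * self.families_per_superfamily
            * self.proteins_per_family
        )


@dataclass
class Dataset:
    spec: FixtureSpec
    records: list[ProteinRecord]
    fold_labels: dict[str, FoldLabel]
    annotations: list[DomainAnnotation]
    clan_map: ClanMap
    residue_embeddings: dict[str, np.ndarray]
    pooled: dict[str, np.ndarray]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def annotation_map(self) -> dict[str, DomainAnnotation]:
        return {a.protein_id: a for a in self.annotations}


def planted_model(spec: FixtureSpec) -> BilinearModel:
    """The bilinear ground truth the labels are generated from.

    W* = (tm_same_fold / d) · I, so two proteins sitting on the same unit-
    variance fold centroid score ≈ tm_same_fold while near-orthogonal
    cross-fold centroids score near zero.
    """
    return BilinearModel(np.eye(spec.dim) * (spec.tm_same_fold / spec.dim))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    letters = list(seq)
    for i in range(len(letters)):
        if rng.random() < rate:
            letters[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(letters)


def make_dataset(spec: FixtureSpec) -> Dataset:
    """Generate the full fixture: sequences, labels, annotations, embeddings."""
    rng = np.random.default_rng(spec.seed)
    d = spec.dim

    records: list[ProteinRecord] = []
    fold_labels: dict[str, FoldLabel] = {}
    annotations: list[DomainAnnotation] = []
    pooled: dict[str, np.ndarray] = {}
    clan_of_family: dict[str, str] = {}

    # power-law weights over the big shared clans (steeper exponent ->
    # heavier concentration in the largest clan)
    big_weights = np.array(
        [1.0 / (k + 1) ** spec.tail_exponent for k in range(spec.n_big_clans)]
    )
    big_weights /= big_weights.sum()

    fam_counter = 0
    for f in range(spec.n_folds):
        fold_name = f"fold{f:02d}"
        fold_clan = f"CL{f:04d}"
        length = int(rng.integers(spec.seq_length[0], spec.seq_length[1] + 1))
        ancestor = "".join(
            AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)
        )
        centroid = rng.standard_normal(d)  # unit variance per coordinate
        for s in range(spec.superfamilies_per_fold):
            sf_name = f"{fold_name}.sf{s}"
            sf_seq = _mutate(ancestor, spec.mutation_rate, rng)
            sf_centroid = centroid + spec.sigma_sf * rng.standard_normal(d)
            for g in range(spec.families_per_superfamily):
                fam_counter += 1
                fam_acc = f"PF{fam_counter:05d}"
                fam_name = f"{sf_name}.fa{g}"
                fam_seq = _mutate(sf_seq, spec.mutation_rate, rng)
                fam_centroid = sf_centroid + spec.sigma_family * rng.standard_normal(d)
                clan_of_family[fam_acc] = fold_clan
                for p in range(spec.proteins_per_family):
                    pid = f"{fam_name}.p{p}"
                    seq = _mutate(fam_seq, spec.mutation_rate, rng)
                    records.append(ProteinRecord(pid, seq))
                    fold_labels[pid] = FoldLabel(pid, fam_name, sf_name, fold_name)
                    pooled[pid] = fam_centroid + spec.sigma_emb * rng.standard_normal(d)
                    fams: set[str] = set()
                    if rng.random() >= spec.p_no_domain:
                        fams.add(fam_acc)
                        if rng.random() < spec.p_extra_domain:
                            k = int(rng.choice(spec.n_big_clans, p=big_weights))
                            fams.add(f"PF9{k:04d}")
                    annotations.append(DomainAnnotation(pid, frozenset(fams)))

    for k in range(spec.n_big_clans):
        clan_of_family[f"PF9{k:04d}"] = f"CL9{k:03d}"

    encoder = MockEncoder(
        EncoderSpec(
            dimension=d,
            deterministic_seed=spec.seed,
            mode="context_free",
            noise=spec.sigma_residue,
        )
    )
    residue = {r.id: encoder.encode(r) for r in records}
    return Dataset(
        spec,
        records,
        fold_labels,
        annotations,
        ClanMap(clan_of_family),
        residue,
        pooled,
    )


def make_recovery_problem(
    n_pairs: int = 5000,
    dim: int = 8,
    n_proteins: int = 400,
    sigma_tm: float = 0.02,
    seed: int = 42,
) -> tuple[list[LabeledPair], dict[str, np.ndarray], BilinearModel]:
    """A parameter-recovery problem with a known bilinear ground truth.

    Embeddings are uniform on [0, 1]^d and W* is a symmetric perturbation of
    (1/4)·I, so the noiseless scores z1ᵀ W* z2 land mostly inside (0, 1);
    labels add N(0, sigma_tm) noise and clamp to [0, 1]. Returns
    (labeled pairs, embeddings, planted model).
    """
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n_proteins)]
    Z = {pid: rng.uniform(0.0, 1.0, dim) for pid in ids}
    W = 0.25 * np.eye(dim) + 0.02 * rng.standard_normal((dim, dim))
    W = (W + W.T) / 2.0
    pairs = []
    for _ in range(n_pairs):
        q, t = rng.choice(ids, 2, replace=False)
        raw = float(Z[q] @ W @ Z[t])
        tm = float(np.clip(raw + sigma_tm * rng.standard_normal(), 0.0, 1.0))
        pairs.append(LabeledPair(q, t, tm))
    return pairs, Z, BilinearModel(W)


def make_training_pairs(
    dataset: Dataset,
    model: BilinearModel | None = None,
    n_pairs: int | None = None,
    seed: int | None = None,
    balance_fraction: float | None = None,
    same_fold_shift: float = 0.0,
    misspecified: bool = False,
) -> list[LabeledPair]:
    """TM-score labels from the planted bilinear form of pooled embeddings.

    label = clamp01(z1ᵀ W* z2 + shift·[same fold] + N(0, sigma_tm)). With
    ``misspecified=True`` labels instead decay exponentially with embedding
    distance (for robustness tests against the bilinear assumption).
    ``balance_fraction`` undersamples sub-threshold (TM <= 0.5) pairs until
    the stated fraction of labels exceeds 0.5, mirroring dataset-level
    balancing of scarce same-fold pairs.
    """
    spec = dataset.spec
    model = model or planted_model(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids = dataset.ids
    all_pairs = [(q, t) for q in ids for t in ids if q != t]
    if n_pairs is not None and n_pairs < len(all_pairs):
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        chosen = [all_pairs[i] for i in sorted(idx)]
    else:
        chosen = all_pairs

    pairs: list[LabeledPair] = []
    for q, t in chosen:
        z1, z2 = dataset.pooled[q], dataset.pooled[t]
        if misspecified:
            raw = float(np.exp(-np.linalg.norm(z1 - z2) / np.sqrt(spec.dim)))
        else:
            raw = float(z1 @ model.W @ z2)
        if same_fold_shift and (
            dataset.fold_labels[q].fold == dataset.fold_labels[t].fold
        ):
            raw += same_fold_shift
        tm = float(np.clip(raw + spec.sigma_tm * rng.standard_normal(), 0.0, 1.0))
        pairs.append(LabeledPair(q, t, tm))

    if balance_fraction is not None:
        pos = [p for p in pairs if p.tm_score > 0.5]
        neg = [p for p in pairs if p.tm_score <= 0.5]
        if pos and balance_fraction > 0:
            want_neg = int(round(len(pos) * (1 - balance_fraction) / balance_fraction))
            if want_neg < len(neg):
                keep = rng.choice(len(neg), size=want_neg, replace=False)
                neg = [neg[i] for i in sorted(keep)]
        pairs = sorted(pos + neg, key=lambda p: (p.query_id, p.target_id))
    return pairs
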