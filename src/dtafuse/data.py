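"""Affinity datasets: reading/writing, the Kd -> pKd transform, splits and
synthetic data with a planted drug-substructure / protein-motif interaction.

Real datasets (Davis / KIBA / BindingDB CSV exports) are read as delimited
tables with ``smiles``, ``protein`` and ``affinity`` columns (remappable).
Davis-style raw dissociation constants in nM are converted to pKd with
``pKd = -log10(Kd / 1e9)``.

The synthetic generator emulates the triplet structure of those datasets at
desk scale: drugs are assembled from a pool of chain-extendable SMILES
fragments, proteins are uniform random amino-acid strings, and the affinity
is ``base + effect * 1[pharmacophore in SMILES and motif in protein] +
N(0, noise)``.  The planted indicator (and the pharmacophore's atom indices)
are recorded so attribution tests have a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from rdkit import Chem

REQUIRED_COLUMNS = ("smiles", "protein", "affinity")


@dataclass
class AffinityRecord:
    """One (drug SMILES, protein sequence, affinity) triplet."""

    smiles: str
    protein: str
    affinity: float
    kd_nM: float | None = None

    def __post_init__(self):
        if not self.smiles or not self.protein:
            raise ValueError("SMILES and protein must be non-empty")
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")


def kd_to_pkd(kd_nM: float) -> float:
    """pKd = -log10(Kd / 1e9) with Kd given in nanomolar."""
    if kd_nM <= 0:
        raise ValueError(f"Kd must be positive, got {kd_nM}")
    return float(-np.log10(kd_nM / 1e9))


def read_affinity_table(path, columns: dict | None = None) -> list[AffinityRecord]:
    """Read a delimited text table of affinity triplets.

    ``columns`` remaps header names, e.g. ``{"smiles": "compound_iso_smiles"}``.
    A ``kd_nM`` column, when present and the affinity column is absent, is
    converted to pKd.  Errors carry 1-based data-row numbers.
    """
    columns = {**{c: c for c in REQUIRED_COLUMNS}, "kd_nM": "kd_nM", **(columns or {})}
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    have_kd = columns["kd_nM"] in frame.columns
    have_affinity = columns["affinity"] in frame.columns
    for logical in ("smiles", "protein"):
        if columns[logical] not in frame.columns:
            raise ValueError(f"missing column {columns[logical]!r} in {path}")
    if not have_affinity and not have_kd:
        raise ValueError(f"need an affinity or kd_nM column in {path}")

    records = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        smiles = row[columns["smiles"]]
        protein = row[columns["protein"]]
        if not smiles or not protein:
            raise ValueError(f"row {row_no}: empty smiles or protein field")
        kd = None
        if have_kd and row[columns["kd_nM"]] != "":
            kd = _parse_float(row[columns["kd_nM"]], row_no, "kd_nM")
        if have_affinity and row[columns["affinity"]] != "":
            affinity = _parse_float(row[columns["affinity"]], row_no, "affinity")
        elif kd is not None:
            affinity = kd_to_pkd(kd)
        else:
            raise ValueError(f"row {row_no}: no affinity value")
        records.append(AffinityRecord(smiles, protein, affinity, kd_nM=kd))
    return records


def _parse_float(text: str, row_no: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"row {row_no}: non-numeric {column} value {text!r}") from None


def write_affinity_table(records, path):
    frame = pd.DataFrame(
        [{"smiles": r.smiles, "protein": r.protein, "affinity": r.affinity,
          **({"kd_nM": r.kd_nM} if r.kd_nM is not None else {})}
         for r in records]
    )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

DEFAULT_FRACTIONS = (4 / 6, 1 / 6, 1 / 6)


@dataclass
class DatasetSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int
    fractions: tuple

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _largest_remainder_sizes(n: int, fractions) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    leftover = n - sum(sizes)
    order = np.argsort([-(e - s) for e, s in zip(exact, sizes)], kind="stable")
    for k in range(leftover):
        sizes[order[k]] += 1
    return sizes


def split_dataset(records, fractions=DEFAULT_FRACTIONS, seed: int = 0) -> DatasetSplit:
    """Seeded uniform shuffle followed by a contiguous partition.

    Part sizes use largest-remainder rounding so they sum to ``len(records)``
    exactly; the default fractions follow a 4:1:1 train/validation/test scheme.
    """
    n = len(records)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n < len(fractions):
        raise ValueError(f"cannot split {n} records into {len(fractions)} parts")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = _largest_remainder_sizes(n, fractions)
    bounds = np.cumsum(sizes)
    return DatasetSplit(
        train=np.sort(perm[: bounds[0]]),
        validation=np.sort(perm[bounds[0]: bounds[1]]),
        test=np.sort(perm[bounds[1]:]),
        seed=seed,
        fractions=tuple(fractions),
    )


def kfold_indices(indices, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold partition of an index set (cross-validation mode).

    Returns (train_idx, val_idx) pairs; folds differ in size by at most one.
    """
    indices = np.asarray(indices)
    if k < 2 or k > len(indices):
        raise ValueError("need 2 <= k <= number of records")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(indices)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        val = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, val))
    return out


def cold_entity_split(records, entity: str = "smiles", fractions=DEFAULT_FRACTIONS,
                      seed: int = 0) -> DatasetSplit:
    """Optional cold-drug / cold-target split: partition by unique entity.

    Not the benchmark protocol (that splits by interaction record); provided
    for generalisation experiments.
    """
    if entity not in ("smiles", "protein"):
        raise ValueError("entity must be 'smiles' or 'protein'")
    keys = [getattr(r, entity) for r in records]
    unique = sorted(set(keys))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    sizes = _largest_remainder_sizes(len(unique), fractions)
    bounds = np.cumsum(sizes)
    groups = [set(), set(), set()]
    for part, chunk in enumerate(np.split(perm, bounds[:-1])):
        groups[part].update(unique[i] for i in chunk)
    idx = [[], [], []]
    for i, key in enumerate(keys):
        for part in range(3):
            if key in groups[part]:
                idx[part].append(i)
                break
    return DatasetSplit(
        train=np.asarray(idx[0]), validation=np.asarray(idx[1]),
        test=np.asarray(idx[2]), seed=seed, fractions=tuple(fractions),
    )


# ---------------------------------------------------------------------------
# Synthetic data with planted signal
# ---------------------------------------------------------------------------

# Chain-extendable fragments: every fragment starts with an atom symbol and can
# be concatenated after any other, so assembled strings are always valid SMILES.
DEFAULT_FRAGMENT_POOL = (
    "C", "CC", "CCC", "CO", "CN", "CCO", "CCN", "C(C)", "CC(C)", "C(O)",
    "C(N)", "COC", "CNC", "C(C)C",
)
#: Trifluoromethyl cap; F is monovalent so the planted fragment terminates the
#: string, and no pool fragment contains F, so the substring occurs iff planted.
DEFAULT_PHARMACOPHORE = "C(F)(F)F"
DEFAULT_MOTIF = "HYWHYW"
SYNTHETIC_PROTEIN_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SyntheticSpec:
    """Generative study conditions for the planted-signal benchmark."""

    n_records: int = 2000
    fragment_pool: tuple = DEFAULT_FRAGMENT_POOL
    protein_alphabet: tuple = SYNTHETIC_PROTEIN_ALPHABET
    pharmacophore: str = DEFAULT_PHARMACOPHORE
    motif: str = DEFAULT_MOTIF
    protein_length: int = 48
    min_fragments: int = 3
    max_fragments: int = 6
    pharmacophore_prob: float = 0.5
    motif_prob: float = 0.5
    base_affinity: float = 5.0
    effect_size: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.motif) >= self.protein_length:
            raise ValueError("motif must be shorter than the protein")
        if not 0 <= self.pharmacophore_prob <= 1 or not 0 <= self.motif_prob <= 1:
            raise ValueError("planting probabilities must lie in [0, 1]")
        for frag in tuple(self.fragment_pool) + (self.pharmacophore,):
            if Chem.MolFromSmiles(frag) is None:
                raise ValueError(f"unparseable fragment in pool: {frag!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fragment_pool"] = list(self.fragment_pool)
        d["protein_alphabet"] = list(self.protein_alphabet)
        return d


def _heavy_atom_count(smiles: str) -> int:
    return Chem.MolFromSmiles(smiles).GetNumAtoms()


def generate_synthetic(spec: SyntheticSpec) -> tuple[list[AffinityRecord], list[dict]]:
    """Generate seeded affinity records plus per-record planted-signal metadata.

    Metadata holds ``has_pharmacophore``, ``has_motif``, ``co_occurrence`` and
    ``pharmacophore_atoms`` (atom indices of the planted substructure in the
    emitted SMILES, empty when absent).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pool = list(spec.fragment_pool)
    records, meta = [], []
    for _ in range(spec.n_records):
        k = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
        fragments = [pool[i] for i in rng.integers(0, len(pool), k)]
        has_pharmacophore = bool(rng.random() < spec.pharmacophore_prob)
        smiles = "".join(fragments)
        pharmacophore_atoms: list[int] = []
        if has_pharmacophore:
            offset = sum(_heavy_atom_count(f) for f in fragments)
            smiles += spec.pharmacophore
            pharmacophore_atoms = list(
                range(offset, offset + _heavy_atom_count(spec.pharmacophore))
            )
        if Chem.MolFromSmiles(smiles) is None:  # defensive; pool is chain-safe
            raise ValueError(f"assembled SMILES failed to parse: {smiles!r}")

        protein = "".join(
            spec.protein_alphabet[i]
            for i in rng.integers(0, len(spec.protein_alphabet), spec.protein_length)
        )
        has_motif = bool(rng.random() < spec.motif_prob)
        if has_motif:
            pos = int(rng.integers(0, spec.protein_length - len(spec.motif) + 1))
            protein = protein[:pos] + spec.motif + protein[pos + len(spec.motif):]

        hit = (spec.pharmacophore in smiles) and (spec.motif in protein)
        affinity = spec.base_affinity + spec.effect_size * hit
        if spec.noise_sd > 0:
            affinity += rng.normal(0.0, spec.noise_sd)
        records.append(AffinityRecord(smiles, protein, float(affinity)))
        meta.append({
            "has_pharmacophore": has_pharmacophore,
            "has_motif": has_motif,
            "co_occurrence": bool(hit),
            "pharmacophore_atoms": pharmacophore_atoms,
        })
    return records, meta
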