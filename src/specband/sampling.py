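"""Dataset construction schemes: session equalization, deliberate sampling
biases, and plant-stratified vs plain random train/test/validation splits.

Four schemes are provided, named after the sampling strategies they emulate:

* ``UD-SS`` — unbiased dataset, stratified (plant-level) split: per-session
  class counts equalized, and no plant contributes tiles to both the training
  and the test side. This is the leakage-free reference condition.
* ``UD-RS`` — unbiased dataset, random split: same equalization, but tiles are
  partitioned ignoring plant identity, so tiles of one plant can appear on
  both sides — the split that lets a classifier exploit plant fingerprints.
* ``BDT-SS`` — biased by treatment: per-session retention fractions differ
  between the two treatments.
* ``BDI-SS`` — biased by imaging session: retention fractions differ across
  sessions but not between treatments.

Fractional retention uses floor(fraction × n), which reproduces the cell
counts of the emulated trial exactly (e.g. 306 → 61 at 20%, 306 → 183 at 60%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SET_FRACTIONS = (0.65, 0.20, 0.15)  # train, test, validation

#: Default biased-by-treatment retention schedule for 5 sessions: keep 20% of
#: deficient tiles in sessions 1-2, 60% of both in session 3, 20% of control
#: tiles in sessions 4-5.
BDT_FRACTIONS = {
    (1, "C"): 1.0, (1, "D"): 0.2,
    (2, "C"): 1.0, (2, "D"): 0.2,
    (3, "C"): 0.6, (3, "D"): 0.6,
    (4, "C"): 0.2, (4, "D"): 1.0,
    (5, "C"): 0.2, (5, "D"): 1.0,
}

#: Default biased-by-imaging retention schedule: 20% from sessions 1-2, 60%
#: from session 3, everything from sessions 4-5 (both treatments alike).
BDI_FRACTIONS = {
    (s, t): f
    for s, f in [(1, 0.2), (2, 0.2), (3, 0.6), (4, 1.0), (5, 1.0)]
    for t in ("C", "D")
}


@dataclass
class BiasSchema:
    """Per-(session, treatment) retention fractions."""

    name: str
    fractions: dict  # (session, treatment) -> fraction in [0, 1]

    def __post_init__(self) -> None:
        for cell, f in self.fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"fraction for cell {cell} outside [0, 1]: {f}")

    def fraction(self, session: int, treatment: str) -> float:
        return self.fractions[(session, treatment)]


@dataclass
class Split:
    """Train/test/validation partition by sample_id."""

    train: list
    test: list
    validation: list
    mode: str  # "stratified" | "random"
    fractions: tuple = SET_FRACTIONS
    seed: int | None = None

    def as_dict(self) -> dict:
        return {"train": list(self.train), "test": list(self.test),
                "validation": list(self.validation), "mode": self.mode,
                "fractions": list(self.fractions), "seed": self.seed}


def _cells(manifest: pd.DataFrame):
    return manifest.groupby(["imaging", "treatment"], sort=True)


def _ordered(manifest: pd.DataFrame) -> pd.DataFrame:
    # canonical row order so results do not depend on input row order
    return manifest.sort_values("sample_id", kind="stable").reset_index(drop=True)


def equalize_sessions(manifest: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Downsample every (session, treatment) cell to the global minimum cell
    size, without replacement, deterministically per seed."""
    manifest = _ordered(manifest)
    sizes = _cells(manifest).size()
    sessions = sorted(manifest["imaging"].unique())
    for s in sessions:
        for t in ("C", "D"):
            if (s, t) not in sizes.index or sizes.loc[(s, t)] == 0:
                raise ValueError(f"empty (session, treatment) cell: ({s}, {t!r})")
    n_star = int(sizes.min())
    rng = np.random.default_rng(seed)
    kept = []
    for _, cell in _cells(manifest):
        idx = rng.choice(len(cell), size=n_star, replace=False)
        kept.append(cell.iloc[np.sort(idx)])
    return pd.concat(kept).reset_index(drop=True)


def apply_bias(manifest: pd.DataFrame, schema: BiasSchema, seed: int) -> pd.DataFrame:
    """Retain floor(fraction × n) samples from each (session, treatment) cell,
    chosen without replacement, deterministically per seed."""
    manifest = _ordered(manifest)
    rng = np.random.default_rng(seed)
    kept = []
    for (s, t), cell in _cells(manifest):
        f = schema.fraction(int(s), str(t))
        n_keep = int(np.floor(f * len(cell)))
        idx = rng.choice(len(cell), size=n_keep, replace=False)
        kept.append(cell.iloc[np.sort(idx)])
    return pd.concat(kept).reset_index(drop=True)


def split_random(manifest: pd.DataFrame, fractions=SET_FRACTIONS,
                 seed: int = 0) -> Split:
    """Sample-level random partition; test and validation counts by floor,
    remainder goes to train."""
    manifest = _ordered(manifest)
    n = len(manifest)
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    n_test = int(np.floor(fractions[1] * n))
    n_val = int(np.floor(fractions[2] * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = manifest["sample_id"].to_numpy()
    test = ids[perm[:n_test]]
    val = ids[perm[n_test:n_test + n_val]]
    train = ids[perm[n_test + n_val:]]
    return Split(sorted(train), sorted(test), sorted(val), "random",
                 tuple(fractions), seed)


def split_stratified(manifest: pd.DataFrame, fractions=SET_FRACTIONS,
                     seed: int = 0) -> Split:
    """Plant-level split: every plant's tiles go whole to one of the three
    sets, so no identifier ever spans the train/test boundary.

    Within each treatment group, plants are ordered by descending tile count
    (seeded shuffle breaks ties) and greedily assigned to the set with the
    largest remaining sample deficit relative to the (0.65, 0.20, 0.15)
    targets; running the assignment per treatment keeps both classes present
    in every set.
    """
    manifest = _ordered(manifest)
    for t in ("C", "D"):
        n_ids = manifest.loc[manifest["treatment"] == t, "identifier"].nunique()
        if n_ids < 3:
            raise ValueError(
                f"need >= 3 distinct plants per treatment, treatment {t!r} has {n_ids}")
    counts = manifest.groupby("identifier").size()
    plant_treatment = manifest.groupby("identifier")["treatment"].first()
    rng = np.random.default_rng(seed)
    plant_set: dict = {}
    for t in ("C", "D"):
        plants = sorted(plant_treatment.index[plant_treatment == t])
        plants = list(np.array(plants)[rng.permutation(len(plants))])
        plants.sort(key=lambda p: -counts.loc[p])  # stable: seeded order breaks ties
        total = int(counts.loc[plants].sum())
        targets = [f * total for f in fractions]
        assigned = [0.0, 0.0, 0.0]
        for p in plants:
            deficits = [tg - a for tg, a in zip(targets, assigned)]
            k = int(np.argmax(deficits))
            plant_set[p] = k
            assigned[k] += counts.loc[p]
    sets: list[list] = [[], [], []]
    for sid, ident in zip(manifest["sample_id"], manifest["identifier"]):
        sets[plant_set[ident]].append(sid)
    return Split(sorted(sets[0]), sorted(sets[1]), sorted(sets[2]),
                 "stratified", tuple(fractions), seed)


SCHEMA_NAMES = ("UD-SS", "UD-RS", "BDT-SS", "BDI-SS")


def build_dataset(manifest: pd.DataFrame, schema_name: str, seed: int,
                  bias_fractions: dict | None = None
                  ) -> tuple[pd.DataFrame, Split]:
    """Compose equalization, optional bias, and the appropriate split.

    ``bias_fractions`` overrides the default 5-session retention schedules
    (required when the manifest does not have exactly sessions 1..5).
    """
    name = schema_name.upper()
    if name not in SCHEMA_NAMES:
        raise ValueError(f"unknown schema {schema_name!r}; expected one of {SCHEMA_NAMES}")
    ss = np.random.SeedSequence(seed).generate_state(3)
    manifest = equalize_sessions(manifest, int(ss[0]))
    if name in ("BDT-SS", "BDI-SS"):
        defaults = BDT_FRACTIONS if name == "BDT-SS" else BDI_FRACTIONS
        schema = BiasSchema(name[:3], bias_fractions or defaults)
        manifest = apply_bias(manifest, schema, int(ss[1]))
    if name == "UD-RS":
        split = split_random(manifest, seed=int(ss[2]))
    else:
        split = split_stratified(manifest, seed=int(ss[2]))
    return manifest, split
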