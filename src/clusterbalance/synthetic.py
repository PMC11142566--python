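"""Seeded generator of imbalanced, clustered, thyroid-style tables.

The generator emulates the features of the reference clinical table that the
balancing method relies on: heavy two-class imbalance (6666 vs 250 by
default), multi-modal continuous structure (a spherical Gaussian mixture, so
elbow selection has a planted answer), class-conditional shifts on the
hormone-like columns (the TSH analogue shifts most, giving importance
rankings a planted truth), class-dependent Bernoulli indicator features, an
all-null junk column mirroring the source file, and optional uniform label
noise so nearest-neighbour editing has something to remove.

:func:`planted_truth` exposes the generating latent structure (cluster
assignments, pre-noise labels, effect-size order) for parameter-recovery
tests.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .tabular import (
    BINARY,
    CONTINUOUS,
    FeatureSchema,
    LabeledTable,
    thyroid_schema,
    write_csv,
)

#: default per-hormone mean shift (in within-cluster sd units) for the
#: minority class.  The TSH analogue dominates by design; the magnitudes are
#: moderate so the classes overlap the way hormone panels overlap the
#: reference range — the regime in which imbalance actually hurts a naive
#: classifier.  Pass a larger ``class_shift`` for a cleanly separable table.
DEFAULT_CLASS_SHIFT = {
    "TSH": 1.5,
    "T3_measured": 1.0,
    "TT4_measured": 0.7,
    "T4U_measured": 0.5,
    "FTI_measured": 0.3,
    "Age": 0.0,
}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_majority: int = 6666
    n_minority: int = 250
    n_binary_features: int = 15
    n_continuous_features: int = 6
    n_clusters: int = 5
    cluster_separation: float = 8.0
    class_shift: dict[str, float] | None = None
    label_noise_frac: float = 0.0
    null_column: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_majority < 0 or self.n_minority < 0:
            raise GeneratorError("class counts must be nonnegative")
        if not 0.0 <= self.label_noise_frac < 0.5:
            raise GeneratorError("label_noise_frac must be in [0, 0.5)")
        n = self.n_majority + self.n_minority
        if self.n_clusters < 1 or self.n_clusters > max(n, 1):
            raise GeneratorError("n_clusters must be in [1, n]")
        if self.n_continuous_features < 1:
            raise GeneratorError("need at least one continuous feature (Age)")


@dataclass(frozen=True)
class PlantedTruth:
    cluster_assignments: np.ndarray
    true_labels: np.ndarray          # pre-noise
    flipped_indices: np.ndarray
    importance_order: tuple[str, ...]  # planted effect size, descending


def _schema_for(cfg: GeneratorConfig) -> FeatureSchema:
    ref = thyroid_schema()
    if (
        cfg.n_binary_features == 15
        and cfg.n_continuous_features == 6
        and cfg.null_column
    ):
        return ref
    cont = list(ref.feature_names[i] for i in np.flatnonzero(ref.continuous_mask))
    binry = [n for n in ref.feature_names if n not in cont and n != "Unnamed:22"]
    cont_names = cont[: cfg.n_continuous_features] + [
        f"hormone_{i}" for i in range(len(cont), cfg.n_continuous_features)
    ]
    nb = cfg.n_binary_features - (1 if cfg.null_column else 0)
    bin_names = binry[:nb] + [f"indicator_{i}" for i in range(len(binry), nb)]
    if cfg.null_column:
        bin_names.append("Unnamed:22")
    names = tuple(cont_names) + tuple(bin_names)
    kinds = (CONTINUOUS,) * len(cont_names) + (BINARY,) * len(bin_names)
    return FeatureSchema(names, kinds)


def _shift_vector(cfg: GeneratorConfig, schema: FeatureSchema) -> np.ndarray:
    shift_map = dict(DEFAULT_CLASS_SHIFT)
    if cfg.class_shift:
        shift_map.update(cfg.class_shift)
    out = np.zeros(schema.d)
    hormone_rank = 0
    for j, (name, kind) in enumerate(zip(schema.feature_names, schema.feature_kinds)):
        if kind != CONTINUOUS:
            continue
        if name in shift_map:
            out[j] = shift_map[name]
        elif name != "Age":
            # generic hormone-like columns decay geometrically from 1.5 sd
            out[j] = 1.5 * (0.7 ** hormone_rank)
        hormone_rank += 1
    return out


def _generate(cfg: GeneratorConfig) -> tuple[LabeledTable, PlantedTruth]:
    schema = _schema_for(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_majority + cfg.n_minority

    y = np.concatenate([np.zeros(cfg.n_majority, int), np.ones(cfg.n_minority, int)])
    perm = rng.permutation(n)
    y = y[perm]

    clusters = rng.integers(0, cfg.n_clusters, size=n)

    cont_cols = np.flatnonzero(schema.continuous_mask)
    bin_cols = np.flatnonzero(schema.binary_mask)
    d_cont = cont_cols.size

    # cluster centres: one-hot layout scaled by the separation; if there are
    # more clusters than continuous dims, reuse dims with flipped sign
    centers = np.zeros((cfg.n_clusters, d_cont))
    for c in range(cfg.n_clusters):
        dim = c % d_cont
        centers[c, dim] = cfg.cluster_separation * (1.0 if c < d_cont else -1.0)

    X = np.empty((n, schema.d))
    X[:, cont_cols] = centers[clusters] + rng.normal(size=(n, d_cont))
    shift = _shift_vector(cfg, schema)
    X[np.ix_(y == 1, cont_cols)] += shift[cont_cols]

    # indicator features: Bernoulli with class-dependent rates
    for rank, j in enumerate(bin_cols):
        name = schema.feature_names[j]
        if name == "Unnamed:22":
            X[:, j] = np.nan
            continue
        p0 = 0.05 + 0.25 * ((rank % 5) / 4.0)
        p1 = min(p0 + 0.12, 0.9)
        p = np.where(y == 1, p1, p0)
        X[:, j] = (rng.random(n) < p).astype(float)

    true_y = y.copy()
    n_flip = int(np.floor(cfg.label_noise_frac * n))
    flipped = rng.choice(n, size=n_flip, replace=False) if n_flip else np.empty(0, int)
    y_noisy = y.copy()
    y_noisy[flipped] = 1 - y_noisy[flipped]

    # planted importance: continuous shift (sd units) and binary rate gap
    # expressed as a standardized mean difference
    effect = np.zeros(schema.d)
    effect[cont_cols] = np.abs(shift[cont_cols])
    for rank, j in enumerate(bin_cols):
        name = schema.feature_names[j]
        if name == "Unnamed:22":
            continue
        p0 = 0.05 + 0.25 * ((rank % 5) / 4.0)
        p1 = min(p0 + 0.12, 0.9)
        effect[j] = abs(p1 - p0) / np.sqrt(p0 * (1 - p0))
    order = np.lexsort((np.arange(schema.d), -effect))
    importance_order = tuple(schema.feature_names[j] for j in order)

    table = LabeledTable(X, y_noisy, schema)
    truth = PlantedTruth(clusters, true_y, np.sort(flipped), importance_order)
    return table, truth


def generate(cfg: GeneratorConfig = GeneratorConfig()) -> LabeledTable:
    """Draw one synthetic imbalanced table (exact class counts pre-noise)."""
    return _generate(cfg)[0]


def planted_truth(cfg: GeneratorConfig = GeneratorConfig()) -> PlantedTruth:
    """The latent structure behind :func:`generate` for the same config."""
    return _generate(cfg)[1]


def write_fixtures(outdir: str | Path, cfg: GeneratorConfig = GeneratorConfig()) -> dict:
    """Write the default synthetic CSV + schema sidecar and the packaged
    expert-opinion fixture tables into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = generate(cfg)
    data_path = outdir / "thyroid_synthetic.csv"
    schema_path = outdir / "thyroid_synthetic.schema.json"
    write_csv(table, data_path)
    table.schema.to_json(schema_path)
    paths = {"data": data_path, "schema": schema_path}
    pkg_data = resources.files("clusterbalance") / "data"
    for name in ("thyroid_interviews.csv", "thyroid_survey.csv", "thyroid_concordance.csv"):
        dest = outdir / name
        shutil.copyfile(str(pkg_data / name), dest)
        paths[name] = dest
    return paths
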