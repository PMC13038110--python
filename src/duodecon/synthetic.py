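"""Synthetic single-cell references, cohorts, and survival data.

The generator emulates an annotated scRNA-seq reference with planted
structure so that every downstream stage (feature selection, pseudobulk
simulation, training, subtyping) can be exercised against known ground
truth: counts follow a negative-binomial model with a shared overdispersion,
each cell type carries a disjoint set of marker genes whose mean is
multiplied by a fold change, and an optional two-condition design shifts a
per-type set of condition DEGs in the second condition.

Survival times are exponential with a per-group hazard multiplier and
independent censoring, the simplest model with controllable hazard ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

__all__ = ["SyntheticSpec", "generate_reference", "split_cells", "generate_survival"]


@dataclass
class SyntheticSpec:
    n_cell_types: int = 6
    n_genes: int = 2000
    cells_per_type: int = 500
    n_markers_per_type: int = 40
    marker_fold_change: float = 8.0
    baseline_mean: float = 2.0
    dispersion: float = 0.3  # phi in var = m + phi m^2
    n_conditions: int = 1
    n_condition_degs: int = 0
    condition_fold_change: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.n_genes < 1 or self.cells_per_type < 1:
            raise ValueError("counts must be positive")
        if self.marker_fold_change <= 0 or self.condition_fold_change <= 0:
            raise ValueError("fold changes must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.n_conditions not in (1, 2):
            raise ValueError("n_conditions must be 1 or 2")
        needed = self.n_cell_types * (self.n_markers_per_type + self.n_condition_degs)
        if needed > self.n_genes:
            raise ValueError(
                f"cannot allocate {needed} disjoint marker/condition-DEG genes "
                f"out of {self.n_genes}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    # gamma-Poisson mixture: var = m + phi m^2
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam).astype(np.int32)


def generate_reference(spec: SyntheticSpec, name: str = "synthetic") -> ad.AnnData:
    """Generate an annotated cells x genes reference as an AnnData.

    ``obs`` holds ``cell_type``, ``split`` (assigned 8:1:1 stratified), and
    ``condition`` for two-condition designs; ``uns['markers']`` and
    ``uns['condition_degs']`` record the planted truth per cell type.
    """
    rng = np.random.default_rng(spec.seed)
    c, g = spec.n_cell_types, spec.n_genes
    types = [f"type{t}" for t in range(c)]
    gene_ids = np.array([f"g{i:05d}" for i in range(g)])

    # per-gene baseline means: lognormal spread around baseline_mean
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    base = spec.baseline_mean * raw / raw.mean()

    # disjoint marker and condition-DEG allocations
    n_special = c * (spec.n_markers_per_type + spec.n_condition_degs)
    special = rng.choice(g, size=n_special, replace=False)
    markers: dict[str, np.ndarray] = {}
    cond_degs: dict[str, np.ndarray] = {}
    pos = 0
    for t in types:
        markers[t] = np.sort(special[pos : pos + spec.n_markers_per_type])
        pos += spec.n_markers_per_type
    for t in types:
        cond_degs[t] = np.sort(special[pos : pos + spec.n_condition_degs])
        pos += spec.n_condition_degs

    n_cells = c * spec.cells_per_type
    counts = np.empty((n_cells, g), dtype=np.int32)
    cell_type = np.repeat(types, spec.cells_per_type)
    condition = np.empty(n_cells, dtype=object)
    row = 0
    for ti, t in enumerate(types):
        mean_t = base.copy()
        mean_t[markers[t]] *= spec.marker_fold_change
        for ci in range(spec.n_conditions):
            n_sub = spec.cells_per_type // spec.n_conditions
            if ci == spec.n_conditions - 1:
                n_sub = spec.cells_per_type - n_sub * (spec.n_conditions - 1)
            mean_tc = mean_t.copy()
            if ci == 1:
                mean_tc[cond_degs[t]] *= spec.condition_fold_change
            counts[row : row + n_sub] = _nb_sample(
                rng, np.broadcast_to(mean_tc, (n_sub, g)), spec.dispersion)
            condition[row : row + n_sub] = f"cond{ci + 1}"
            row += n_sub

    obs = pd.DataFrame({
        "cell_type": pd.Categorical(cell_type, categories=types),
        "condition": condition.astype(str),
    }, index=[f"cell{i:06d}" for i in range(n_cells)])
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    ref = ad.AnnData(X=counts, obs=obs, var=var)
    ref.uns["name"] = name
    ref.uns["markers"] = {t: gene_ids[m].tolist() for t, m in markers.items()}
    ref.uns["condition_degs"] = {t: gene_ids[m].tolist() for t, m in cond_degs.items()}
    return split_cells(ref, (0.8, 0.1, 0.1), seed=spec.seed)


def split_cells(ref: ad.AnnData, ratio=(0.8, 0.1, 0.1), seed: int = 0) -> ad.AnnData:
    """Assign train/val/test tags, stratified by cell type.

    Within each cell type the three counts are the largest-remainder
    apportionment of the requested fractions, so they match the exact
    fractions within one cell.  A cell type with fewer cells than occupied
    split slots goes entirely to train, with a warning.
    """
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0) or not np.isclose(ratio.sum(), 1.0):
        raise ValueError("split fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    names = np.array(["train", "val", "test"])
    split = np.empty(ref.n_obs, dtype=object)
    for t in ref.obs["cell_type"].cat.categories:
        idx = np.flatnonzero((ref.obs["cell_type"] == t).to_numpy())
        n = idx.size
        if n == 0:
            continue
        n_slots = int(np.count_nonzero(ratio))
        if n < n_slots:
            warnings.warn(f"cell type {t!r} has only {n} cells; all assigned to train")
            split[idx] = "train"
            continue
        exact = ratio * n
        alloc = np.floor(exact).astype(int)
        rem = exact - alloc
        for _ in range(n - alloc.sum()):
            j = int(np.argmax(rem))
            alloc[j] += 1
            rem[j] = -1
        perm = rng.permutation(idx)
        split[perm] = np.repeat(names, alloc)
    out = ref.copy()
    out.obs["split"] = pd.Categorical(split.astype(str), categories=list(names))
    return out


def generate_survival(groups, effect: dict, censor_rate: float = 0.2,
                      seed: int = 0, baseline_hazard: float = 1.0) -> pd.DataFrame:
    """Exponential survival with per-group hazard multipliers.

    ``groups`` maps each patient to a label (a pandas Series or a dict);
    ``effect`` maps each label to a positive hazard multiplier.  Each patient
    is independently censored with probability ``censor_rate``, in which case
    the observed time is uniform on (0, event time).
    """
    groups = pd.Series(groups)
    for lab in groups.unique():
        if lab not in effect:
            raise ValueError(f"no hazard multiplier for group {lab!r}")
        if effect[lab] <= 0:
            raise ValueError(f"hazard multiplier for {lab!r} must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hazards = groups.map(effect).to_numpy(dtype=float) * baseline_hazard
    t_event = rng.exponential(1.0 / hazards)
    censored = rng.random(groups.size) < censor_rate
    u = rng.random(groups.size)
    time = np.where(censored, t_event * u, t_event)
    time = np.maximum(time, np.finfo(float).tiny)  # strictly positive
    return pd.DataFrame({
        "patient_id": groups.index.astype(str),
        "time": time,
        "event": (~censored).astype(int),
    })
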