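"""Pseudobulk simulation with ground-truth proportions and per-type GEPs.

For every sample a proportion vector is drawn from a Dirichlet distribution
(symmetric alpha=25 for evenly distributed proportions; alpha=7 on one
uniformly chosen type and 1 elsewhere for one dominant cell type), cell
counts per type are drawn multinomially, cells are sampled uniformly with
replacement within type, and the pseudobulk is the average raw-count vector
over all sampled cells.  The ground-truth per-type GEP columns are the
per-type averages over the same sampled cells, so in count space

    b_counts = sum_t p_target[t] * G_counts[:, t]

holds exactly, with p_target the realized multinomial fractions.  Inputs and
GEP targets are mapped to the model's space by library-size normalization to
counts-per-million followed by log2(x + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import h5py
import numpy as np

__all__ = [
    "SimulationConfig",
    "PseudobulkSet",
    "sample_proportions",
    "simulate_pseudobulk",
    "normalize_log_cpm",
    "subset_genes",
    "concat_sets",
]


@dataclass
class SimulationConfig:
    n_samples: int = 2000
    cells_per_sample: int = 500
    alpha_mode: str = "even"       # "even" or "dominant"
    alpha_even: float = 25.0
    alpha_dominant: float = 7.0
    mixed_reference_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_mode not in ("even", "dominant"):
            raise ValueError("alpha_mode must be 'even' or 'dominant'")
        if not 0 <= self.mixed_reference_fraction <= 1:
            raise ValueError("mixed_reference_fraction must be in [0, 1]")
        if self.n_samples < 1 or self.cells_per_sample < 1:
            raise ValueError("n_samples and cells_per_sample must be positive")


@dataclass
class PseudobulkSet:
    """Arrays for n simulated samples over g genes and c cell types."""

    b_counts: np.ndarray   # (n, g) average raw counts over sampled cells
    b_input: np.ndarray    # (n, g) log2 CPM
    p_target: np.ndarray   # (n, c) realized proportions
    p_drawn: np.ndarray    # (n, c) Dirichlet draws
    G_target: np.ndarray   # (n, g, c) log2 CPM per-type GEPs (0 where absent)
    type_mask: np.ndarray  # (n, c) type present among sampled cells
    source: np.ndarray     # (n,) reference name or "mixed"
    cell_types: list[str]
    gene_ids: list[str]
    split: str
    condition: str | None = None
    cells_used: list | None = None  # per-sample global cell indices (provenance audit)

    @property
    def n_samples(self) -> int:
        return self.b_counts.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for k in ("b_counts", "b_input", "p_target", "p_drawn", "G_target", "type_mask"):
                f.create_dataset(k, data=getattr(self, k), compression="gzip")
            f.create_dataset("source", data=np.array(self.source, dtype="S"))
            f.attrs["cell_types"] = self.cell_types
            f.attrs["gene_ids"] = self.gene_ids
            f.attrs["split"] = self.split
            f.attrs["condition"] = self.condition if self.condition is not None else ""

    def export_tsv(self, outdir) -> None:
        """Write the set as delimited matrices: inputs (genes x samples),
        realized proportions, and per-sample ground-truth GEPs."""
        import pathlib

        import pandas as pd

        outdir = pathlib.Path(outdir)
        (outdir / "geps").mkdir(parents=True, exist_ok=True)
        samples = [f"sample{i:04d}" for i in range(self.n_samples)]
        pd.DataFrame(self.b_input.T, index=pd.Index(self.gene_ids, name="gene"),
                     columns=samples).to_csv(outdir / "b_input.tsv", sep="\t")
        pd.DataFrame(self.p_target, index=pd.Index(samples, name="sample"),
                     columns=self.cell_types).to_csv(outdir / "p_target.tsv", sep="\t")
        for i, s in enumerate(samples):
            pd.DataFrame(self.G_target[i], index=pd.Index(self.gene_ids, name="gene"),
                         columns=self.cell_types).to_csv(
                outdir / "geps" / f"{s}.tsv", sep="\t")

    @classmethod
    def load(cls, path) -> "PseudobulkSet":
        with h5py.File(path, "r") as f:
            kw = {k: f[k][...] for k in
                  ("b_counts", "b_input", "p_target", "p_drawn", "G_target", "type_mask")}
            kw["source"] = f["source"][...].astype(str)
            kw["cell_types"] = list(f.attrs["cell_types"])
            kw["gene_ids"] = list(f.attrs["gene_ids"])
            kw["split"] = str(f.attrs["split"])
            cond = str(f.attrs["condition"])
            kw["condition"] = cond if cond else None
        return cls(**kw)


def normalize_log_cpm(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """log2(1e6 * x / sum(x) + 1): library-size normalization to CPM then log2.

    Scale-invariant in the library size; raises on an all-zero profile rather
    than silently returning zeros.
    """
    x = np.asarray(x, dtype=np.float64)
    total = x.sum(axis=axis, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cannot normalize a profile with zero total counts")
    return np.log2(1e6 * x / total + 1.0)


def sample_proportions(c: int, config: SimulationConfig, n: int,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n proportion vectors over c cell types from the configured Dirichlet.

    Even mode uses a symmetric concentration ``alpha_even``; dominant mode
    picks one type uniformly at random per draw and gives it concentration
    ``alpha_dominant`` with 1 elsewhere.
    """
    if c < 1:
        raise ValueError("need at least one cell type")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if c == 1:
        return np.ones((n, 1))
    if config.alpha_mode == "even":
        alpha = np.full((n, c), config.alpha_even)
    else:
        alpha = np.ones((n, c))
        alpha[np.arange(n), rng.integers(0, c, size=n)] = config.alpha_dominant
    gam = rng.gamma(alpha)
    return gam / gam.sum(axis=1, keepdims=True)


def _counts_matrix(ref: ad.AnnData) -> np.ndarray:
    X = ref.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X)


def _cell_pools(refs, split, condition, cell_types):
    """Per-source, per-type arrays of usable cell row indices (plus global ids)."""
    pools = []
    offset = 0
    for ref in refs:
        keep = (ref.obs["split"] == split).to_numpy()
        if condition is not None:
            keep &= (ref.obs["condition"] == condition).to_numpy()
        by_type = {}
        for t in cell_types:
            rows = np.flatnonzero(keep & (ref.obs["cell_type"] == t).to_numpy())
            if rows.size:
                by_type[t] = (rows, rows + offset)
        pools.append(by_type)
        offset += ref.n_obs
    return pools


def simulate_pseudobulk(refs, split: str, config: SimulationConfig,
                        condition: str | None = None,
                        track_cells: bool = False) -> PseudobulkSet:
    """Simulate a pseudobulk set from the given split of one or more references.

    With several references, ``round(n_samples * mixed_reference_fraction)``
    samples pool cells across all of them (source tag ``"mixed"``); the rest
    are allocated to single references as evenly as possible.  Cells tagged
    with other splits never contribute.
    """
    if isinstance(refs, ad.AnnData):
        refs = [refs]
    if not refs:
        raise ValueError("need at least one reference")
    gene_ids = list(refs[0].var_names)
    for r in refs[1:]:
        if list(r.var_names) != gene_ids:
            raise ValueError("references must share an identical gene axis")
    cell_types = sorted({t for r in refs for t in r.obs["cell_type"].cat.categories})
    c = len(cell_types)
    g = len(gene_ids)
    n = config.n_samples
    rng = np.random.default_rng(config.seed)

    mats = [_counts_matrix(r) for r in refs]
    names = [str(r.uns.get("name", f"ref{i}")) for i, r in enumerate(refs)]
    pools = _cell_pools(refs, split, condition, cell_types)
    mixed_pool: dict[str, list] = {}
    for si, by_type in enumerate(pools):
        for t, (rows, gids) in by_type.items():
            mixed_pool.setdefault(t, []).append((si, rows, gids))
    for t in cell_types:
        if t not in mixed_pool:
            raise ValueError(f"cell type {t!r} has no cells in split {split!r}")

    # source assignment: deterministic allocation, then shuffled positions
    if len(refs) > 1:
        n_mixed = int(round(n * config.mixed_reference_fraction))
    else:
        n_mixed = 0
    src_idx = np.full(n, -1, dtype=int)  # -1 = mixed
    singles = n - n_mixed
    per_ref = np.full(len(refs), singles // len(refs))
    per_ref[: singles % len(refs)] += 1
    src_idx[n_mixed:] = np.repeat(np.arange(len(refs)), per_ref)

    p_drawn = sample_proportions(c, config, n, rng)
    b_counts = np.zeros((n, g))
    p_target = np.zeros((n, c))
    G_counts = np.zeros((n, g, c))
    type_mask = np.zeros((n, c), dtype=bool)
    source = np.empty(n, dtype=object)
    cells_used = [] if track_cells else None

    for i in range(n):
        si = src_idx[i]
        source[i] = "mixed" if si < 0 else names[si]
        n_per_type = rng.multinomial(config.cells_per_sample, p_drawn[i])
        used_i = []
        for ti, t in enumerate(cell_types):
            m = n_per_type[ti]
            if m == 0:
                continue
            if si >= 0:
                if t not in pools[si]:
                    raise ValueError(
                        f"cell type {t!r} drawn for source {names[si]!r} but absent "
                        f"from its split {split!r}")
                rows, gids = pools[si][t]
                pick = rng.integers(0, rows.size, size=m)
                col = mats[si][rows[pick]].sum(axis=0)
                if track_cells:
                    used_i.append(gids[pick])
            else:
                entries = mixed_pool[t]
                sizes = np.array([r.size for _, r, _ in entries])
                flat = rng.integers(0, sizes.sum(), size=m)
                col = np.zeros(g)
                bounds = np.concatenate([[0], np.cumsum(sizes)])
                for (sj, rows, gids), lo, hi in zip(entries, bounds[:-1], bounds[1:]):
                    sel = flat[(flat >= lo) & (flat < hi)] - lo
                    if sel.size:
                        col += mats[sj][rows[sel]].sum(axis=0)
                        if track_cells:
                            used_i.append(gids[sel])
            G_counts[i, :, ti] = col / m
            p_target[i, ti] = m / config.cells_per_sample
            type_mask[i, ti] = True
        b_counts[i] = G_counts[i] @ p_target[i]
        if b_counts[i].sum() <= 0:
            raise ValueError(f"sample {i} drew zero total counts")
        if track_cells:
            cells_used.append(np.concatenate(used_i))

    b_input = normalize_log_cpm(b_counts, axis=1)
    G_target = np.zeros_like(G_counts)
    present = type_mask & (G_counts.sum(axis=1) > 0)
    for ti in range(c):
        rows = np.flatnonzero(present[:, ti])
        if rows.size:
            G_target[rows, :, ti] = normalize_log_cpm(G_counts[rows, :, ti], axis=1)

    return PseudobulkSet(
        b_counts=b_counts, b_input=b_input, p_target=p_target, p_drawn=p_drawn,
        G_target=G_target, type_mask=type_mask, source=source.astype(str),
        cell_types=cell_types, gene_ids=gene_ids, split=split,
        condition=condition, cells_used=cells_used)


def concat_sets(sets: list[PseudobulkSet]) -> PseudobulkSet:
    """Stack pseudobulk sets simulated from the same reference split setup.

    Sets may differ in condition (recorded per sample as the source suffix);
    they must agree on genes, cell types, and split.
    """
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.gene_ids != first.gene_ids or s.cell_types != first.cell_types:
            raise ValueError("pseudobulk sets disagree on genes or cell types")
        if s.split != first.split:
            raise ValueError("refusing to concatenate sets from different splits")
    conds = {s.condition for s in sets}
    source = np.concatenate([
        s.source if s.condition is None
        else np.array([f"{src}|{s.condition}" for src in s.source])
        for s in sets])
    return PseudobulkSet(
        b_counts=np.concatenate([s.b_counts for s in sets]),
        b_input=np.concatenate([s.b_input for s in sets]),
        p_target=np.concatenate([s.p_target for s in sets]),
        p_drawn=np.concatenate([s.p_drawn for s in sets]),
        G_target=np.concatenate([s.G_target for s in sets]),
        type_mask=np.concatenate([s.type_mask for s in sets]),
        source=source,
        cell_types=first.cell_types, gene_ids=first.gene_ids, split=first.split,
        condition=conds.pop() if len(conds) == 1 else None,
        cells_used=None)


def subset_genes(pb: PseudobulkSet, genes) -> PseudobulkSet:
    """Restrict a pseudobulk set to an ordered gene list (after normalization).

    Normalization happened on the full gene axis, mirroring how a real bulk
    library is normalized on the whole transcriptome before feature selection.
    """
    index = {gid: i for i, gid in enumerate(pb.gene_ids)}
    missing = [gid for gid in genes if gid not in index]
    if missing:
        raise KeyError(f"genes absent from the pseudobulk set: {missing[:5]}...")
    rows = np.array([index[gid] for gid in genes])
    return PseudobulkSet(
        b_counts=pb.b_counts[:, rows], b_input=pb.b_input[:, rows],
        p_target=pb.p_target, p_drawn=pb.p_drawn,
        G_target=pb.G_target[:, rows, :], type_mask=pb.type_mask,
        source=pb.source, cell_types=pb.cell_types, gene_ids=list(genes),
        split=pb.split, condition=pb.condition, cells_used=pb.cells_used)
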