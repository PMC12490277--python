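"""Readers and writers: observation CSV, adjacency files, chain exports.

Observation CSV schema (long format, one row per region-year-outcome
cell): columns ``region, year, outcome, count, censored, cens_low,
cens_high, population``.  Censored rows leave ``count`` empty and carry
the inclusive interval in ``cens_low``/``cens_high``.

Adjacency comes either as a two-column edge-list CSV of region labels or
as a GAL neighbor file (header line with the region count; then, per
region, a "label degree" line followed by a line of neighbor labels).
Region index order is taken from the adjacency file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import AdjacencyGraph, build_adjacency
from .mcmc import MCMCConfig, PosteriorChains
from .model import ObservationData

__all__ = [
    "read_edge_csv",
    "write_edge_csv",
    "read_gal",
    "write_gal",
    "read_adjacency",
    "observation_data_from_frame",
    "observation_data_to_frame",
    "read_observation_csv",
    "write_observation_csv",
    "load_dataset",
    "write_chains",
    "read_chains",
    "load_run_config",
]


# ----------------------------------------------------------------------
# adjacency
# ----------------------------------------------------------------------
def read_edge_csv(path) -> AdjacencyGraph:
    """Edge-list CSV with two label columns; labels indexed in file order."""
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("edge-list CSV needs two label columns")
    a, b = frame.columns[:2]
    labels: list = []
    for lab in pd.concat([frame[a], frame[b]]):
        if lab not in labels:
            labels.append(lab)
    index = {lab: i for i, lab in enumerate(labels)}
    edges = [(index[r], index[s]) for r, s in zip(frame[a], frame[b])]
    return build_adjacency(edges, len(labels), labels=labels)


def write_edge_csv(graph: AdjacencyGraph, path) -> None:
    rows = [(graph.labels[i], graph.labels[l]) for (i, l) in graph.edges]
    pd.DataFrame(rows, columns=["region_a", "region_b"]).to_csv(path, index=False)


def read_gal(path) -> AdjacencyGraph:
    """GAL neighbor file; tolerates the common 1- and 4-token headers."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[1]) if len(header) == 4 else int(header[0])
    labels = []
    neigh = {}
    pos = 1
    for _ in range(n):
        lab, deg = lines[pos].split()[:2]
        labels.append(lab)
        neigh[lab] = lines[pos + 1].split() if int(deg) > 0 else []
        if int(deg) != len(neigh[lab]):
            raise ValueError(f"GAL degree mismatch for region {lab}")
        pos += 2
    index = {lab: i for i, lab in enumerate(labels)}
    edges = []
    for lab, nbrs in neigh.items():
        for nb in nbrs:
            if nb not in index:
                raise ValueError(f"GAL neighbor {nb!r} of {lab!r} is not a listed region")
            edges.append((index[lab], index[nb]))
    return build_adjacency(edges, n, labels=labels)


def write_gal(graph: AdjacencyGraph, path) -> None:
    nbrs = {lab: [] for lab in graph.labels}
    for (i, l) in graph.edges:
        nbrs[graph.labels[i]].append(graph.labels[l])
        nbrs[graph.labels[l]].append(graph.labels[i])
    out = [str(graph.n_regions)]
    for lab in graph.labels:
        out.append(f"{lab} {len(nbrs[lab])}")
        out.append(" ".join(nbrs[lab]))
    Path(path).write_text("\n".join(out) + "\n")


def read_adjacency(path) -> AdjacencyGraph:
    """Dispatch on extension: .gal -> GAL, anything else -> edge CSV."""
    return read_gal(path) if str(path).endswith(".gal") else read_edge_csv(path)


# ----------------------------------------------------------------------
# observations
# ----------------------------------------------------------------------
_REQUIRED = ["region", "year", "outcome", "count", "censored", "population"]


def observation_data_from_frame(
    frame: pd.DataFrame,
    region_order=None,
    reference_outcome=None,
) -> ObservationData:
    """Build :class:`ObservationData` from the long-format table."""
    for col in _REQUIRED:
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    frame = frame.copy()
    frame["region"] = frame["region"].astype(str)
    regions = (
        [str(r) for r in region_order]
        if region_order is not None
        else list(dict.fromkeys(frame["region"]))
    )
    unknown = set(frame["region"]) - set(regions)
    if unknown:
        rows = frame.index[frame["region"].isin(unknown)].tolist()[:5]
        raise ValueError(f"unknown region label(s) {sorted(unknown)} at rows {rows}")
    years = sorted(frame["year"].unique())
    outcomes = list(dict.fromkeys(frame["outcome"].astype(str)))
    N, J, K = len(regions), len(years), len(outcomes)
    ridx = {r: i for i, r in enumerate(regions)}
    yidx = {y: j for j, y in enumerate(years)}
    oidx = {o: k for k, o in enumerate(outcomes)}

    counts = np.full((N, J, K), np.nan)
    censored = np.zeros((N, J, K), dtype=bool)
    cens_low = np.zeros((N, J, K), dtype=np.int64)
    cens_high = np.zeros((N, J, K), dtype=np.int64)
    missing = np.ones((N, J, K), dtype=bool)
    populations = np.ones((N, J))

    records = frame.to_dict("records")
    for rownum, row in enumerate(records):
        i, j, k = ridx[row["region"]], yidx[row["year"]], oidx[str(row["outcome"])]
        missing[i, j, k] = False
        populations[i, j] = row["population"]
        if int(row["censored"]):
            censored[i, j, k] = True
            cens_low[i, j, k] = int(row["cens_low"])
            cens_high[i, j, k] = int(row["cens_high"])
        else:
            c = row["count"]
            if pd.isna(c):
                raise ValueError(f"row {rownum}: uncensored cell without a count")
            if c < 0:
                raise ValueError(f"row {rownum}: negative count {c}")
            counts[i, j, k] = float(c)

    if "offset" in frame.columns:
        offsets = np.full((N, J, K), np.nan)
        for row in records:
            offsets[ridx[row["region"]], yidx[row["year"]], oidx[str(row["outcome"])]] = row[
                "offset"
            ]
        if np.any(np.isnan(offsets[~missing])):
            raise ValueError("offset column present but incomplete")
        offsets = np.where(np.isnan(offsets), 1.0, offsets)
    else:
        # derive baseline rates from the first year's observed totals
        from .simulate import compute_expected_counts

        base = np.nan_to_num(counts[:, 0, :])
        _, offsets = compute_expected_counts(populations, base)

    ref = 0
    if reference_outcome is not None:
        ref = (
            outcomes.index(str(reference_outcome))
            if not isinstance(reference_outcome, int)
            else reference_outcome
        )
    return ObservationData(
        counts=counts,
        offsets=offsets,
        populations=populations,
        censored=censored,
        cens_low=cens_low,
        cens_high=cens_high,
        missing=missing,
        region_labels=regions,
        years=years,
        outcome_labels=outcomes,
        reference_outcome=ref,
    )


def observation_data_to_frame(data: ObservationData) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(data.region_labels):
        for j, y in enumerate(data.years):
            for k, o in enumerate(data.outcome_labels):
                if data.missing[i, j, k]:
                    continue
                cens = bool(data.censored[i, j, k])
                rows.append(
                    {
                        "region": r,
                        "year": y,
                        "outcome": o,
                        "count": None if cens else int(data.counts[i, j, k]),
                        "censored": int(cens),
                        "cens_low": int(data.cens_low[i, j, k]) if cens else "",
                        "cens_high": int(data.cens_high[i, j, k]) if cens else "",
                        "population": data.populations[i, j],
                        "offset": data.offsets[i, j, k],
                    }
                )
    return pd.DataFrame(rows)


def read_observation_csv(path, region_order=None, reference_outcome=None) -> ObservationData:
    return observation_data_from_frame(
        pd.read_csv(path), region_order=region_order, reference_outcome=reference_outcome
    )


def write_observation_csv(data: ObservationData, path) -> None:
    observation_data_to_frame(data).to_csv(path, index=False)


def load_dataset(data_path, adjacency_path, reference_outcome=None):
    """Load and index-align observations and adjacency.

    Region label order is taken from the adjacency file.
    """
    graph = read_adjacency(adjacency_path)
    data = read_observation_csv(
        data_path, region_order=list(graph.labels), reference_outcome=reference_outcome
    )
    return data, graph


# ----------------------------------------------------------------------
# chains
# ----------------------------------------------------------------------
def write_chains(chains: PosteriorChains, outdir) -> None:
    """One long-format CSV per parameter block plus a YAML config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in chains.draws.items():
        n_chains, n_stored = arr.shape[:2]
        comp_shape = arr.shape[2:]
        idx_cols = [f"index_{d}" for d in range(len(comp_shape))]
        grid = [np.arange(s) for s in comp_shape]
        mesh = np.meshgrid(*grid, indexing="ij") if grid else []
        flat_idx = [m.ravel() for m in mesh]
        records = []
        for c in range(n_chains):
            for t in range(n_stored):
                vals = arr[c, t].ravel() if comp_shape else np.array([arr[c, t]])
                rec = {"chain": c, "iteration": t, "value": vals}
                for col, iv in zip(idx_cols, flat_idx):
                    rec[col] = iv
                records.append(pd.DataFrame(rec))
        pd.concat(records, ignore_index=True).to_csv(outdir / f"{name}.csv", index=False)
    meta = {
        "config": {
            k: (v if not isinstance(v, (np.integer, np.floating)) else float(v))
            for k, v in vars(chains.config).items()
        },
        "acceptance": chains.acceptance,
        "chain_seeds": [int(s) for s in chains.chain_seeds],
        "runtime_seconds": float(chains.runtime_seconds),
        "region_labels": list(chains.region_labels),
        "outcome_labels": list(chains.outcome_labels),
        "years": [int(y) for y in chains.years],
        "shapes": {k: list(v.shape) for k, v in chains.draws.items()},
    }
    (outdir / "run.yaml").write_text(yaml.safe_dump(meta))


def read_chains(outdir) -> PosteriorChains:
    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / "run.yaml").read_text())
    draws = {}
    for name, shape in meta["shapes"].items():
        frame = pd.read_csv(outdir / f"{name}.csv")
        arr = np.empty(shape)
        idx_cols = [c for c in frame.columns if c.startswith("index_")]
        order = ["chain", "iteration"] + sorted(idx_cols) + ["value"]
        frame = frame[order].sort_values(order[:-1])
        arr.flat = frame["value"].to_numpy()
        draws[name] = arr
    return PosteriorChains(
        draws=draws,
        config=MCMCConfig(**meta["config"]),
        acceptance=meta["acceptance"],
        chain_seeds=meta["chain_seeds"],
        runtime_seconds=meta["runtime_seconds"],
        region_labels=meta["region_labels"],
        outcome_labels=meta["outcome_labels"],
        years=meta["years"],
    )


def load_run_config(path) -> dict:
    """YAML (or JSON, a YAML subset) run configuration."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg
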