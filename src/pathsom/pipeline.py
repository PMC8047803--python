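"""End-to-end workflow: features → SOM → clusters → traces → graph → maps.

Stages write their artifacts into the run directory and are resumable: a
stage whose artifact files already exist is loaded instead of recomputed,
so deleting a downstream artifact and re-running regenerates only the
downstream stages.  Everything is deterministic given the config and its
seed, and the summary records a hash of the config it was produced from.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ContactPairSet, FeatureMatrix, extract_features, load_structure, select_native_pairs
from .paths import PathTrace, cluster_paths, linkage_to_newick, trace_path
from .som import SOMModel, cluster_neurons, train_som
from .synthetic import ToyUnfoldingSpec, generate_dataset
from .transition import build_graph, map_property, transition_matrix, work_profile

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; every analysis parameter is a named key
    with the method's standard value as default."""

    out_dir: str
    seed: int
    # input: either synthetic (default) or real structure + trajectories
    synthetic: bool = True
    n_per_pathway: tuple[int, ...] = (12, 38)
    native_pdb: str | None = None
    model_index: int = 1
    trajectories: tuple[str, ...] = ()
    # featurization
    cutoff: float = 1.0  # nm
    stride: int = 1
    gly_to_ca: bool = True
    # SOM
    rows: int = 8
    cols: int = 8
    n_epochs: int = 500
    # clustering
    neuron_clusters: int | str = 8
    path_clusters: int = 2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("cutoff", "stride", "rows", "cols", "n_epochs", "path_clusters"):
            if getattr(self, name) is not None and np.asarray(getattr(self, name)).min() <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.synthetic and not self.native_pdb:
            raise ValueError("real-data runs need native_pdb")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        raw = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.items()
        }
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow and return the machine-readable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: features ------------------------------------------------
    pairs_path = out / "native_pairs.csv"
    feats_dir = out / "features"
    feats_dir.mkdir(exist_ok=True)
    labels_true: list[str] | None = None
    forces: list[np.ndarray | None] = []
    extensions: list[np.ndarray | None] = []

    if config.synthetic:
        spec = ToyUnfoldingSpec(seed=config.seed)
        dataset = generate_dataset(spec, config.n_per_pathway, seed=config.seed)
        pairs = dataset.pairs
        feature_sets = [r.features for r in dataset.replicas]
        forces = [r.force for r in dataset.replicas]
        extensions = [r.extension for r in dataset.replicas]
        labels_true = dataset.labels
    else:
        native = load_structure(config.native_pdb, config.model_index, config.gly_to_ca)
        pairs = select_native_pairs(native, config.cutoff)
        feature_sets = [
            extract_features(config.native_pdb, pairs, traj, stride=config.stride,
                             replica_id=Path(traj).stem, gly_to_ca=config.gly_to_ca)
            for traj in config.trajectories
        ]
        forces = [None] * len(feature_sets)
        extensions = [None] * len(feature_sets)
    if not pairs_path.exists():
        pairs.to_csv(pairs_path)
    for fm in feature_sets:
        p = feats_dir / f"{fm.replica_id}.csv"
        if not p.exists():
            fm.to_csv(p)
    if not feature_sets:
        raise RuntimeError("stage features: no input trajectories")

    # -- stage 2: SOM training --------------------------------------------
    model_path = out / "som.model"
    all_values = np.vstack([fm.values for fm in feature_sets])
    if model_path.exists():
        model = SOMModel.load(model_path)
    else:
        try:
            model = train_som(all_values, rows=config.rows, cols=config.cols,
                              seed=config.seed, n_epochs=config.n_epochs)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage train failed on pooled features: {exc}") from exc
        model.save(model_path)

    # -- stage 3: neuron clustering ----------------------------------------
    nc_path = out / "neuron_clusters.csv"
    if nc_path.exists():
        nc_df = pd.read_csv(nc_path)
        neuron_labels = nc_df["cluster"].to_numpy()
        avg_sil = float(nc_df["avg_silhouette"].iloc[0])
        n_clusters = int(neuron_labels.max())
    else:
        nc = cluster_neurons(model, n=config.neuron_clusters)
        neuron_labels, avg_sil, n_clusters = nc.labels, nc.average_silhouette, nc.n_clusters
        pd.DataFrame(
            {
                "neuron": np.arange(model.n_neurons),
                "cluster": nc.labels,
                "silhouette": nc.silhouette,
                "avg_silhouette": nc.average_silhouette,
            }
        ).to_csv(nc_path, index=False)

    # -- stage 4: traces ----------------------------------------------------
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    traces: list[PathTrace] = []
    for fm, force, ext in zip(feature_sets, forces, extensions):
        p = traces_dir / f"{fm.replica_id}.csv"
        if p.exists():
            traces.append(PathTrace.from_csv(p, replica_id=fm.replica_id))
        else:
            tr = trace_path(model, fm, force=force, extension=ext)
            tr.to_csv(p)
            traces.append(tr)

    # -- stage 5: pathway clustering ----------------------------------------
    labels_path = out / "path_labels.csv"
    if labels_path.exists():
        path_labels = pd.read_csv(labels_path)["cluster"].to_numpy()
    else:
        pc = cluster_paths(traces, model, n=config.path_clusters)
        path_labels = pc.labels
        pd.DataFrame({"replica": pc.replica_ids, "cluster": pc.labels}).to_csv(labels_path, index=False)
        (out / "path_dendrogram.nwk").write_text(linkage_to_newick(pc.linkage_matrix, pc.replica_ids))

    # -- stage 6: transition graph + property maps --------------------------
    tg = transition_matrix(traces, model.n_neurons)
    pd.DataFrame(tg.counts).to_csv(out / "transition_counts.csv", index=False)
    pd.DataFrame(tg.stochastic).to_csv(out / "transition_stochastic.csv", index=False)
    graph = build_graph(tg)
    edges = pd.DataFrame(
        [(u, v, d["weight"], d["probability"]) for u, v, d in graph.edges(data=True)],
        columns=["from", "to", "neg_log_p", "probability"],
    )
    edges.to_csv(out / "graph_edges.csv", index=False)
    import networkx as nx

    nx.write_graphml(graph, out / "graph.graphml")

    force_map_argmax = None
    if any(tr.force is not None for tr in traces):
        pm = map_property(traces, model.n_neurons, scalar="force")
        pm.to_csv(out / "force_map.csv")
        force_map_argmax = pm.argmax_neuron()
        works = {}
        for tr in traces:
            if tr.force is not None and tr.extension is not None:
                works[tr.replica_id] = float(work_profile(tr.force, tr.extension)[-1])
        pd.Series(works, name="total_work_kJ_mol").to_csv(out / "total_work.csv")

    # -- summary -------------------------------------------------------------
    summary = {
        "config_hash": config.digest(),
        "pathsom_version": __version__,
        "seed": config.seed,
        "n_pairs": len(pairs),
        "n_replicas": len(traces),
        "n_frames_total": int(all_values.shape[0]),
        "quantization_error": model.quantization_error,
        "neuron_cluster_count": n_clusters,
        "neuron_avg_silhouette": round(float(avg_sil), 12),  # stable across CSV reload
        "path_labels": {tr.replica_id: int(lab) for tr, lab in zip(traces, path_labels)},
        "force_argmax_neuron": force_map_argmax,
    }
    if labels_true is not None:
        from sklearn.metrics import adjusted_rand_score

        summary["true_labels"] = {tr.replica_id: lab for tr, lab in zip(traces, labels_true)}
        summary["pathway_ari"] = float(adjusted_rand_score(labels_true, path_labels))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
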