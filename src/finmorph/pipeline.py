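"""File-based pipeline stages: simulate, features, cluster, regions, stats.

Each stage reads and writes plain files only (SWC, TSV, CSV, JSON, Newick),
so stages can be re-run independently and a complete run is reproducible:
with a fixed seed and config, two runs produce byte-identical outputs.

Every stage writes a small JSON *manifest* recording the configuration
snapshot, the seed, SHA-256 hashes of its inputs, its output paths and the
package version; CSV outputs carry the manifest name in a leading ``#``
comment line and JSON outputs in a ``_manifest`` key.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fin_geometry import (
    FinLandmarkSet,
    assign_region_lengths,
    axial_overlap,
    build_model_fin,
    build_regions,
    fit_plane,
    read_landmarks,
    register_model_fin,
    write_landmarks,
)
from .morphometry import FEATURE_COLUMNS, feature_vector, restricted_length
from .stats_clustering import (
    correlation_terminals,
    dendrogram_to_newick,
    leave_one_feature_out,
    length_comparison,
    linkage_to_merge_table,
    silhouette_select_k,
    standardize,
    trend_test,
    ward_cluster,
)
from .swc_io import (
    FIN_LABELS,
    read_annotations,
    read_metadata,
    read_swc,
    write_annotations,
    write_metadata,
    write_swc,
)
from .synthetic_data import Cohort, GeneratorConfig, generate_cohort

__all__ = [
    "RunManifest",
    "simulate",
    "run_features",
    "run_cluster",
    "run_regions",
    "run_stats",
    "run_all",
]

log = logging.getLogger("finmorph")


# ---------------------------------------------------------------------------
# Manifest plumbing
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    seed: int | None
    config: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    version: str = __version__

    @property
    def filename(self) -> str:
        return f"{self.stage}_manifest.json"

    def add_inputs(self, paths: Sequence[Path]) -> None:
        for p in sorted(paths):
            self.inputs[str(p.name)] = _sha256(p)

    def write(self, out_dir: Path) -> Path:
        path = out_dir / self.filename
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    body = df.to_csv(index=False)
    path.write_text(f"# manifest: {manifest.filename}\n{body}")
    manifest.outputs.append(path.name)


def _write_json(obj: dict, path: Path, manifest: RunManifest) -> None:
    obj = dict(obj)
    obj["_manifest"] = manifest.filename
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    manifest.outputs.append(path.name)


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Stage: simulate
# ---------------------------------------------------------------------------

def simulate(config: GeneratorConfig, out_dir: str | Path) -> Cohort:
    """Generate a synthetic cohort and write it in the real pipeline's formats."""
    out = Path(out_dir)
    (out / "swc").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "landmarks").mkdir(exist_ok=True)
    cohort = generate_cohort(config)
    manifest = RunManifest(
        stage="simulate", seed=config.seed, config=asdict(config)
    )
    for sn in cohort:
        write_swc(sn.tree, out / "swc" / f"{sn.neuron_id}.swc")
        write_annotations(sn.tree, out / "annotations" / f"{sn.neuron_id}.tsv")
        write_landmarks(sn.landmarks, out / "landmarks" / f"{sn.neuron_id}.csv")
        manifest.outputs.extend(
            [
                f"swc/{sn.neuron_id}.swc",
                f"annotations/{sn.neuron_id}.tsv",
                f"landmarks/{sn.neuron_id}.csv",
            ]
        )
    write_metadata([sn.metadata for sn in cohort], out / "metadata.csv")
    manifest.outputs.append("metadata.csv")
    truth = {
        sn.neuron_id: {
            "regime": sn.ground_truth.regime,
            "fin_length_um": sn.ground_truth.fin_length,
            "axial_length_um": sn.ground_truth.axial_length,
            "n_fin_branch_points": sn.ground_truth.n_fin_branch_points,
        }
        for sn in cohort
    }
    _write_json(truth, out / "ground_truth.json", manifest)
    manifest.write(out)
    return cohort


# ---------------------------------------------------------------------------
# Stage: features
# ---------------------------------------------------------------------------

def _iter_neurons(swc_dir: Path, annotations_dir: Path | None):
    """Yield (neuron_id, tree) for every readable SWC; collect per-file errors."""
    errors: dict[str, str] = {}
    for swc_path in sorted(swc_dir.glob("*.swc")):
        neuron_id = swc_path.stem
        try:
            tree = read_swc(swc_path)
            if annotations_dir is not None:
                ann = annotations_dir / f"{neuron_id}.tsv"
                if ann.exists():
                    tree = read_annotations(ann, tree)
            yield neuron_id, tree
        except Exception as exc:  # keep going, summarize at the end
            errors[neuron_id] = str(exc)
            log.error("skipping %s: %s", neuron_id, exc)
    if errors:
        log.warning("skipped %d unreadable neurons: %s", len(errors), sorted(errors))


def run_features(
    swc_dir: str | Path,
    annotations_dir: str | Path,
    metadata_csv: str | Path,
    out_dir: str | Path,
    restriction: Sequence[str] | str = FIN_LABELS,
    local_offset: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compute the 13-parameter feature table (one row per neuron).

    Neurons that never branch in the fin keep their row but are flagged
    ``clusterable = False``, mirroring the exclusion of fin-unbranched cells
    from classification.
    """
    swc_dir, annotations_dir = Path(swc_dir), Path(annotations_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not any(swc_dir.glob("*.swc")):
        raise FileNotFoundError(f"no SWC files in {swc_dir}")
    meta = read_metadata(metadata_csv)
    manifest = RunManifest(
        stage="features",
        seed=seed,
        config={"restriction": list(restriction) if restriction != "all" else "all",
                "local_offset": local_offset},
    )
    manifest.add_inputs(list(swc_dir.glob("*.swc")) + [Path(metadata_csv)])
    rows = []
    for neuron_id, tree in _iter_neurons(swc_dir, annotations_dir):
        if neuron_id not in meta:
            raise KeyError(f"no metadata row for neuron {neuron_id}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = feature_vector(tree, meta[neuron_id], restriction, local_offset)
        row = fv.to_dict()
        row["clusterable"] = fv.clusterable
        rows.append(row)
    df = pd.DataFrame(rows, columns=["neuron_id", *FEATURE_COLUMNS, "clusterable"])
    _write_csv(df, out / "features.csv", manifest)
    manifest.write(out)
    return df


# ---------------------------------------------------------------------------
# Stage: cluster
# ---------------------------------------------------------------------------

def run_cluster(
    features_csv: str | Path,
    out_dir: str | Path,
    variant: str = "ward.D2",
    k_max: int = 8,
    seed: int | None = None,
) -> dict[str, Any]:
    """Standardize, Ward-cluster and silhouette-select k; write labels + dendrogram."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _read_csv(features_csv)
    work = df[df["clusterable"].astype(bool)].reset_index(drop=True)
    if len(work) < 3:
        raise ValueError(f"need at least 3 clusterable neurons, have {len(work)}")
    manifest = RunManifest(
        stage="cluster", seed=seed, config={"variant": variant, "k_max": k_max}
    )
    manifest.add_inputs([Path(features_csv)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z, _scaler = standardize(work[FEATURE_COLUMNS])
        link = ward_cluster(z, variant)
        k_range = range(2, min(k_max, len(work) - 1) + 1)
        assignment = silhouette_select_k(z, link, k_range)
        stability = leave_one_feature_out(z, variant, k_range)

    labels = pd.DataFrame(
        {"neuron_id": work["neuron_id"], "cluster": assignment.labels}
    )
    _write_csv(labels, out / "cluster_labels.csv", manifest)
    sil = pd.DataFrame(
        sorted(assignment.silhouettes.items()), columns=["k", "mean_silhouette"]
    )
    _write_csv(sil, out / "silhouette.csv", manifest)
    _write_csv(linkage_to_merge_table(link), out / "merge_table.csv", manifest)
    _write_csv(stability, out / "feature_stability.csv", manifest)
    newick = dendrogram_to_newick(link, list(work["neuron_id"]))
    (out / "dendrogram.nwk").write_text(newick + "\n")
    manifest.outputs.append("dendrogram.nwk")
    summary = {
        "n_clusterable": int(len(work)),
        "n_excluded": int((~df["clusterable"].astype(bool)).sum()),
        "selected_k": int(assignment.k),
        "mean_silhouette": assignment.mean_silhouette,
        "cluster_sizes": {
            str(c): int(n)
            for c, n in zip(*np.unique(assignment.labels, return_counts=True))
        },
    }
    _write_json(summary, out / "cluster_summary.json", manifest)
    manifest.write(out)
    return summary


# ---------------------------------------------------------------------------
# Stage: regions
# ---------------------------------------------------------------------------

def run_regions(
    swc_dir: str | Path,
    annotations_dir: str | Path,
    landmarks_dir: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Octant innervation tables and model-fin axial overlap for every neuron.

    Neurons without a landmark file are skipped with a warning.  A per-neuron
    conservation check (octant sum vs. fin-restricted total length) is
    executed and reported in the overlap table.
    """
    swc_dir = Path(swc_dir)
    annotations_dir = Path(annotations_dir)
    landmarks_dir = Path(landmarks_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(stage="regions", seed=seed, config={})
    manifest.add_inputs(
        list(swc_dir.glob("*.swc")) + list(landmarks_dir.glob("*.csv"))
    )

    neurons = []
    for neuron_id, tree in _iter_neurons(swc_dir, annotations_dir):
        lm_path = landmarks_dir / f"{neuron_id}.csv"
        if not lm_path.exists():
            log.warning("no landmarks for %s; skipped", neuron_id)
            continue
        landmarks = read_landmarks(lm_path)
        plane = fit_plane(landmarks)
        neurons.append((neuron_id, tree, landmarks, plane))

    model = build_model_fin([(lm, pl) for _, _, lm, pl in neurons])

    region_rows = []
    overlap_rows = []
    for neuron_id, tree, landmarks, plane in neurons:
        partition = build_regions(landmarks, plane)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = assign_region_lengths(tree, partition)
        region_rows.append(table.to_dataframe(neuron_id))

        fin_total = restricted_length(tree, FIN_LABELS)
        octant_sum = table.fin_total_length()
        rel_err = (
            abs(octant_sum - fin_total) / fin_total if fin_total > 0 else 0.0
        )

        fm2 = plane.to_2d(landmarks.ring("fm"))
        base_mid = 0.5 * (fm2[0] + fm2[8])
        d = fm2[8] - fm2[0]
        base_angle = math.degrees(math.atan2(d[1], d[0]))
        placed = register_model_fin(model, base_mid, base_angle)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            within, percent = axial_overlap(tree, placed, plane)
        overlap_rows.append(
            {
                "neuron_id": neuron_id,
                "axial_um": table.axial_length,
                "under_fin_um": within,
                "percent": percent,
                "conservation_rel_err": rel_err,
            }
        )

    regions_df = (
        pd.concat(region_rows, ignore_index=True) if region_rows else pd.DataFrame()
    )
    overlap_df = pd.DataFrame(overlap_rows)
    _write_csv(regions_df, out / "regions.csv", manifest)
    _write_csv(overlap_df, out / "overlap.csv", manifest)
    manifest.write(out)
    return regions_df, overlap_df


# ---------------------------------------------------------------------------
# Stage: stats
# ---------------------------------------------------------------------------

def run_stats(
    regions_csv: str | Path,
    features_csv: str | Path,
    metadata_csv: str | Path,
    out_dir: str | Path,
    exclude_population: str | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """The cohort-level statistical report.

    Computes the Pearson correlation of medial-surface fin terminal counts
    with axial under-fin terminal counts, the anteroposterior trend of total
    fin afferent length (with and without the Rohon-Beard cells), and the
    axial-vs-fin total length comparison (chi-square as printed, plus the
    paired Wilcoxon alternative).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = _read_csv(regions_csv)
    features = _read_csv(features_csv)
    meta = read_metadata(metadata_csv)
    manifest = RunManifest(
        stage="stats",
        seed=seed,
        config={"exclude_population": exclude_population},
    )
    manifest.add_inputs([Path(regions_csv), Path(features_csv), Path(metadata_csv)])

    report: dict[str, Any] = {}
    skipped: dict[str, str] = {}

    octants = regions[~regions["region"].isin(["axial", "axial_under_fin"])]
    fin_totals = octants.groupby("neuron_id")["length_um"].sum()
    medial_terminals = (
        octants[octants["surface"] == "medial"].groupby("neuron_id")["terminals"].sum()
    )
    axial = regions[regions["region"] == "axial"].set_index("neuron_id")
    under = regions[regions["region"] == "axial_under_fin"].set_index("neuron_id")

    # neurons with reconstructed axial innervation
    with_axial = axial.index[axial["length_um"] > 0]
    try:
        x = medial_terminals.loc[with_axial].to_numpy()
        y = under.loc[with_axial, "terminals"].to_numpy()
        r, p = correlation_terminals(x, y)
        report["terminal_correlation"] = {"r": r, "p": p, "n": int(len(x))}
    except ValueError as exc:
        skipped["terminal_correlation"] = str(exc)

    feats = features.set_index("neuron_id")
    ids = [i for i in feats.index if i in meta]
    lengths = feats.loc[ids, "total_length"].to_numpy(dtype=float)
    positions = np.array([meta[i].ap_position for i in ids])
    populations = np.array([meta[i].population for i in ids], dtype=object)
    for key, exclude in (("trend_all", frozenset()), ("trend_without_rb", frozenset({"RB"}))):
        try:
            res = trend_test(lengths, positions, populations, exclude)
            report[key] = {
                "F": res.F,
                "p": res.p,
                "slope_um_per_um": res.slope,
                "anterior_higher": bool(res.slope < 0),
                "n": res.n,
            }
        except ValueError as exc:
            skipped[key] = str(exc)

    keep = [
        i
        for i in with_axial
        if not (exclude_population and meta[i].population == exclude_population)
    ]
    try:
        comparison = length_comparison(
            axial.loc[keep, "length_um"].to_numpy(),
            fin_totals.loc[keep].to_numpy(),
        )
        report["axial_vs_fin_length"] = comparison
    except (ValueError, KeyError) as exc:
        skipped["axial_vs_fin_length"] = str(exc)

    if skipped:
        report["skipped"] = skipped
    _write_json(report, out / "statistics.json", manifest)
    manifest.write(out)
    return report


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_all(
    config: GeneratorConfig,
    out_dir: str | Path,
    variant: str = "ward.D2",
    k_max: int = 8,
    exclude_population: str | None = None,
) -> dict[str, Any]:
    """simulate → features → cluster → regions → stats, all under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    simulate(config, out)
    run_features(out / "swc", out / "annotations", out / "metadata.csv", out,
                 seed=config.seed)
    cluster_summary = run_cluster(
        out / "features.csv", out, variant=variant, k_max=k_max, seed=config.seed
    )
    run_regions(out / "swc", out / "annotations", out / "landmarks", out,
                seed=config.seed)
    stats_report = run_stats(
        out / "regions.csv",
        out / "features.csv",
        out / "metadata.csv",
        out,
        exclude_population=exclude_population,
        seed=config.seed,
    )
    return {"cluster": cluster_summary, "stats": stats_report}
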