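"""Descriptive layers of the atlas.

Detection follows the atlas convention: a gene is detectably expressed in a
tissue when its mean TPM over that tissue's replicates strictly exceeds 1;
a gene's expression breadth is the number of tissues where it is detected.
Cluster profiles are per-tissue means over member genes, labelled by tissue
order of descending mean ("omasum > rumen > reticulum" style), with flat
profiles labelled "general".
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .io import ensure_outdir, read_matrix, write_matrix
from .models import ClusterAssignment, ExpressionMatrix, VALID_BIOTYPES
from .network import tissue_average


@dataclass
class DetectionSummary:
    per_tissue: pd.DataFrame    # index tissue; n_detected, fraction_protein_coding
    per_gene: pd.Series         # gene → number of tissues with detection
    detection_threshold: float


@dataclass
class ClusterProfile:
    cluster_id: int
    mean_profile: pd.Series     # tissue → mean TPM over member genes
    label: str
    top_tissue_share: float


def detection_summary(expression: ExpressionMatrix,
                      biotypes: Optional[Mapping[str, str]] = None,
                      threshold: float = 1.0) -> DetectionSummary:
    """Per-tissue and per-gene detection statistics at mean TPM > threshold."""
    tm = tissue_average(expression)
    detected = tm > threshold
    per_gene = detected.sum(axis=1).astype(int)
    per_gene.index.name = "gene_id"

    if biotypes is None:
        bio = pd.Series("protein_coding", index=tm.index)
    else:
        bio = pd.Series({g: biotypes.get(g, "other") for g in tm.index})
        unknown = sorted(set(bio) - set(VALID_BIOTYPES))
        if unknown:
            warnings.warn(f"unknown biotype values treated as 'other': {unknown}")
            bio[bio.isin(unknown)] = "other"
    coding = bio == "protein_coding"
    n_coding = int(coding.sum())
    rows = []
    for t in tm.columns:
        n_det = int(detected[t].sum())
        frac = float(detected.loc[coding, t].sum()) / n_coding if n_coding else 0.0
        rows.append({"tissue": t, "n_detected": n_det,
                     "fraction_protein_coding": frac})
    per_tissue = pd.DataFrame(rows).set_index("tissue")
    return DetectionSummary(per_tissue=per_tissue, per_gene=per_gene,
                            detection_threshold=threshold)


def cluster_profiles(clusters: ClusterAssignment, tissue_matrix: pd.DataFrame,
                     label_depth: int = 5, general_share: float = 0.25) -> list:
    """Mean tissue profile and specificity label per cluster.

    The label lists tissues by descending mean ("t1 > t2 > …", truncated at
    ``label_depth``); clusters whose top tissue holds less than
    ``general_share`` of the profile mass are labelled "general".
    """
    out = []
    for i, members in enumerate(clusters.clusters, start=1):
        missing = sorted(set(members) - set(tissue_matrix.index))
        if missing:
            raise ValueError(f"cluster {i} genes absent from tissue matrix: {missing[:5]}")
        profile = tissue_matrix.loc[sorted(members)].mean(axis=0)
        total = float(profile.sum())
        share = float(profile.max()) / total if total > 0 else 0.0
        ranked = profile.sort_values(ascending=False, kind="mergesort")
        if share < general_share:
            label = "general"
        else:
            label = " > ".join(ranked.index[:label_depth])
        out.append(ClusterProfile(cluster_id=i, mean_profile=profile,
                                  label=label, top_tissue_share=share))
    return out


ATLAS_FILES = ("atlas.tsv", "clusters.tsv", "detection_per_tissue.tsv",
               "cluster_profiles.tsv")


def export_atlas(expression: ExpressionMatrix, detection: DetectionSummary,
                 clusters: ClusterAssignment, outdir, profiles: Optional[list] = None,
                 force: bool = False) -> dict:
    """Write the combined atlas tables; returns the paths written.

    ``atlas.tsv`` holds gene rows, per-sample TPM columns and the per-gene
    "Expression summary" tissue-breadth column.  All files round-trip
    through :func:`read_atlas`.
    """
    ensure_outdir(outdir, force=force, expected=ATLAS_FILES)
    paths = {name: os.path.join(outdir, name) for name in ATLAS_FILES}

    atlas = expression.data.copy()
    atlas["Expression summary"] = detection.per_gene.reindex(atlas.index).fillna(0).astype(int)
    write_matrix(atlas, paths["atlas.tsv"])

    membership = clusters.membership()
    pd.DataFrame({
        "cluster_id": membership.values, "gene_id": membership.index,
    }).sort_values(["cluster_id", "gene_id"]).to_csv(
        paths["clusters.tsv"], sep="\t", index=False)

    detection.per_tissue.to_csv(paths["detection_per_tissue.tsv"], sep="\t",
                                float_format="%.6f")

    if profiles:
        prof = pd.DataFrame(
            {p.cluster_id: p.mean_profile for p in profiles}
        ).T
        prof.index.name = "cluster_id"
        prof["label"] = [p.label for p in profiles]
        prof["top_tissue_share"] = [round(p.top_tissue_share, 6) for p in profiles]
        prof.to_csv(paths["cluster_profiles.tsv"], sep="\t", float_format="%.6f")
    else:
        with open(paths["cluster_profiles.tsv"], "w") as fh:
            fh.write("cluster_id\tlabel\ttop_tissue_share\n")
    return paths


def read_atlas(outdir) -> dict:
    """Read back what :func:`export_atlas` wrote."""
    atlas = read_matrix(os.path.join(outdir, "atlas.tsv"))
    breadth = atlas["Expression summary"].astype(int)
    data = atlas.drop(columns=["Expression summary"])
    clusters = pd.read_csv(os.path.join(outdir, "clusters.tsv"), sep="\t")
    per_tissue = pd.read_csv(os.path.join(outdir, "detection_per_tissue.tsv"),
                             sep="\t", index_col=0)
    return {"expression": data, "breadth": breadth, "clusters": clusters,
            "detection_per_tissue": per_tissue}


def plot_cluster_profiles(profiles, outdir, force: bool = False) -> list:
    """One PNG per cluster profile (requires matplotlib; optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for p in profiles:
        path = os.path.join(outdir, f"cluster_{p.cluster_id:03d}.png")
        if os.path.exists(path) and not force:
            raise FileExistsError(path)
        fig, ax = plt.subplots(figsize=(6, 3))
        p.mean_profile.plot.bar(ax=ax, color="#3b6ea5")
        ax.set_ylabel("mean TPM")
        ax.set_title(f"cluster {p.cluster_id}: {p.label}")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
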