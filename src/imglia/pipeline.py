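"""End-to-end orchestration: config in, report bundle out.

A single structured config (YAML/JSON, key: value) names either real
inputs (count + metadata TSVs for a test and a reference dataset, plus
signature gene lists) or a ``simulation`` block, and per-stage
parameters.  ``run_pipeline`` executes the full validation chain —
normalization, VST, batch removal, rescaling, embedding + clustering,
signature cascade, presence Venn, differential expression, optional
qPCR — and writes every artifact plus a machine-readable
``summary.json`` holding the stage counts and the exact thresholds
used.  Reruns with the same seed are byte-identical.

For cluster purity, samples are labelled by cell *identity* rather than
dataset-specific group name: reference monocytes count as monocytes and
reference microglia as microglia, because co-clustering of same-identity
samples across studies is precisely the outcome under test.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from .containers import ConfigurationError, CountMatrix, GeneList, normalize_symbol
from .de import de_test, volcano_classify
from .embed import (
    classical_mds,
    cluster_purity,
    hierarchical_cluster,
    nearest_centroid,
    pca,
    sample_distances,
)
from .normalize import (
    normalize_counts,
    remove_batch_effect,
    rescale_unit_interval,
    size_factors_median_of_ratios,
    vst_transform,
)
from .qpcr import ddct_fold_change
from .signature import signature_cascade
from .simulate import SimulationConfig, generate_counts, generate_ct_table
from .venn import expressed_genes, venn_partition

__all__ = ["run_pipeline", "load_config", "IDENTITY_CLASSES"]

IDENTITY_CLASSES = {
    "monocyte": "monocyte",
    "ref_monocyte": "monocyte",
    "iMac": "macrophage",
    "iMG": "microglia",
    "ref_microglia": "microglia",
}

_TOP_KEYS = {"seed", "simulation", "inputs", "stages", "qpcr", "output_dir"}
_STAGE_KEYS = {"vst_dispersion", "presence_cutoff", "cascade", "volcano", "embedding", "de"}


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    return validate_config(cfg)


def _load_data(cfg: Mapping[str, Any]):
    """Returns (merged CountMatrix, signature GeneList, vst dispersion hint)."""
    if "simulation" in cfg:
        sim_kwargs = dict(cfg["simulation"])
        sim_kwargs.setdefault("seed", cfg.get("seed", 0))
        if "library_size_range" in sim_kwargs:
            sim_kwargs["library_size_range"] = tuple(sim_kwargs["library_size_range"])
        sim_cfg = SimulationConfig(**sim_kwargs)
        study = generate_counts(sim_cfg)
        sig = GeneList.from_symbols("planted_signature", study.truth_signature)
        return study.counts, sig, sim_cfg.dispersion
    inputs = cfg["inputs"]
    for key in ("counts", "metadata", "ref_counts", "ref_metadata"):
        if key not in inputs:
            raise ConfigurationError(f"inputs block missing {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    test = iio.read_counts(inputs["counts"], inputs["metadata"])
    ref = iio.read_counts(inputs["ref_counts"], inputs["ref_metadata"])
    merged = iio.merge_datasets(test, ref)
    lists = [iio.read_gene_list(p) for p in inputs.get("signature_lists", [])]
    if not lists:
        raise ConfigurationError("inputs block must name at least one signature list")
    sig = iio.union_gene_lists(lists, name="signature_union")
    return merged, sig, None


def _split_by_study(merged: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    studies = list(dict.fromkeys(merged.sample_meta["study"]))
    if len(studies) < 2:
        raise ConfigurationError("pipeline expects samples from at least two studies")
    test_ids = merged.sample_meta.index[merged.sample_meta["study"] == studies[0]]
    ref_ids = merged.sample_meta.index[merged.sample_meta["study"] != studies[0]]
    return merged.subset_samples(test_ids), merged.subset_samples(ref_ids)


def run_pipeline(config: str | Path | Mapping[str, Any], output_dir: str | Path | None = None) -> dict[str, Any]:
    """Run the full validation pipeline; returns the summary dict.

    ``config`` is a path to a YAML/JSON config or an equivalent mapping.
    All artifacts are written under ``output_dir`` (argument overrides
    the config key).
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(dict(config))
    out = Path(output_dir or cfg.get("output_dir", "imglia_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", {})

    merged, sig, sim_dispersion = _load_data(cfg)
    test, ref = _split_by_study(merged)
    iio.write_counts(merged, out / "counts.tsv", out / "sample_meta.tsv")
    iio.write_gene_list(sig, out / "signature_union.txt")

    # --- normalization chain -------------------------------------------
    factors = size_factors_median_of_ratios(merged)
    norm = normalize_counts(merged, factors)
    dispersion = stages.get("vst_dispersion") or sim_dispersion or 0.1
    vst = vst_transform(merged, dispersion=float(dispersion), f=factors)
    # Protect cell identity, not the study-specific group label: labels are
    # nested within study (iMG only in the test study, ref_microglia only in
    # the reference), which would alias the batch term, whereas identities
    # (monocyte/macrophage/microglia) span both studies.
    identity = merged.sample_meta["cell_type"].map(lambda c: IDENTITY_CLASSES.get(c, c))
    corrected = remove_batch_effect(vst, keep=identity)
    rescaled = rescale_unit_interval(corrected)
    iio.write_normalized(rescaled, out / "normalized.tsv", out / "transform_log.json")

    # --- embedding + clustering on the signature genes -----------------
    emb_cfg = stages.get("embedding", {})
    sig_in_data = sorted(
        g for g in rescaled.gene_ids if normalize_symbol(g) in sig.symbols
    )
    sub = rescaled.values.loc[sig_in_data]
    sig_matrix = rescaled.with_transform(sub, "subset_signature", n_genes=len(sig_in_data))
    dist = sample_distances(sig_matrix, metric=emb_cfg.get("metric", "euclidean"))
    k_axes = int(emb_cfg.get("k", 2))
    mds = classical_mds(dist, k=k_axes)
    pcs = pca(sig_matrix, k=k_axes)
    dendro = hierarchical_cluster(dist, linkage=emb_cfg.get("linkage", "average"))

    k_classes = identity.nunique()
    purity = cluster_purity(dendro, identity, k=k_classes)

    centroid_groups = {
        ct: merged.samples_of(ct)
        for ct in ("ref_microglia", "ref_monocyte")
        if (merged.sample_meta["cell_type"] == ct).any()
    }
    nearest = None
    if len(centroid_groups) >= 2 and (merged.sample_meta["cell_type"] == "iMG").any():
        nearest = nearest_centroid(mds, merged.samples_of("iMG"), centroid_groups)

    mds.coordinates.rename_axis("sample_id").to_csv(out / "mds.tsv", sep="\t")
    pcs.coordinates.rename_axis("sample_id").to_csv(out / "pca.tsv", sep="\t")
    pd.DataFrame(dendro.merges, columns=["a", "b", "height", "size"]).to_csv(
        out / "dendrogram.tsv", sep="\t", index=False
    )

    # --- signature cascade ---------------------------------------------
    cas_cfg = stages.get("cascade", {})
    cascade = signature_cascade(
        test,
        ref,
        sig,
        fc_cut=float(cas_cfg.get("fc_cut", 1.2)),
        p_cut=float(cas_cfg.get("p_cut", 0.001)),
        expr_cut=float(cas_cfg.get("expr_cut", 5.0)),
        cons_cut=float(cas_cfg.get("cons_cut", 0.50)),
    )
    cascade.records.rename_axis("gene").to_csv(out / "consistency.tsv", sep="\t")
    for stage, genes in cascade.gene_sets.items():
        (out / f"cascade_{stage}.txt").write_text("\n".join(sorted(genes)) + "\n")

    # --- presence Venn over the test-study cell types ------------------
    presence_cut = float(stages.get("presence_cutoff", 10.0))
    test_norm = normalize_counts(test, size_factors_median_of_ratios(test))
    test_types = [
        ct for ct in ("monocyte", "iMac", "iMG") if (test.sample_meta["cell_type"] == ct).any()
    ]
    venn_counts: dict[str, int] = {}
    if len(test_types) == 3:
        sets = [expressed_genes(test_norm, ct, cutoff=presence_cut) for ct in test_types]
        part = venn_partition(*sets, set_names=tuple(test_types))
        venn_counts = part.counts
        rows = [
            {"region": region, "gene": gene}
            for region in part.regions
            for gene in sorted(part.regions[region])
        ]
        pd.DataFrame(rows, columns=["region", "gene"]).to_csv(
            out / "venn_regions.tsv", sep="\t", index=False
        )
        (out / "venn_counts.json").write_text(json.dumps(venn_counts, indent=2, sort_keys=True))

    # --- differential expression + volcano -----------------------------
    vol_cfg = stages.get("volcano", {})
    de = cascade.de_table
    de.rename_axis("gene").to_csv(out / "de_results.tsv", sep="\t")
    volcano = volcano_classify(
        de,
        p_cut=float(vol_cfg.get("p_cut", 1e-16)),
        lfc_cut=float(vol_cfg.get("lfc_cut", 2.0)),
    )
    volcano.rename_axis("gene").to_csv(out / "volcano.tsv", sep="\t")

    # --- optional qPCR block -------------------------------------------
    qpcr_summary = None
    if "qpcr" in cfg:
        qcfg = cfg["qpcr"]
        if "simulation" in qcfg:
            qsim = dict(qcfg["simulation"])
            qsim.setdefault("seed", seed)
            ct_table = generate_ct_table(**qsim)
        else:
            ct_table = iio.read_ct_table(qcfg["ct_table"])
        ct_table.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        fc = ddct_fold_change(ct_table, treated=qcfg["treated"], control=qcfg["control"])
        qpcr_summary = {
            "treated": qcfg["treated"],
            "control": qcfg["control"],
            "fold_mean": round(fc.mean, 6),
            "fold_sd": round(fc.sd, 6),
        }

    summary = {
        "seed": seed,
        "n_genes": len(merged.gene_ids),
        "n_samples": len(merged.sample_ids),
        "thresholds": {
            "presence_cutoff": presence_cut,
            "cascade": {k: cascade.params[k] for k in ("fc_cut", "p_cut", "expr_cut", "cons_cut")},
            "volcano": volcano.attrs["thresholds"],
            "vst_dispersion": float(dispersion),
        },
        "cascade_stage_counts": cascade.stage_counts,
        "venn_counts": venn_counts,
        "n_volcano_significant": int(volcano["significant"].sum()),
        "cluster_purity": round(float(purity), 6),
        "n_identity_classes": int(k_classes),
        "img_nearest_reference_centroid": nearest,
        "mds_explained": [round(float(v), 6) for v in mds.explained],
        "qpcr": qpcr_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def validate_config(cfg: dict[str, Any]) -> dict[str, Any]:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigurationError("unknown config keys: " + ", ".join(sorted(unknown)))
    unknown_stage = set(cfg.get("stages", {})) - _STAGE_KEYS
    if unknown_stage:
        raise ConfigurationError("unknown stage keys: " + ", ".join(sorted(unknown_stage)))
    if "simulation" not in cfg and "inputs" not in cfg:
        raise ConfigurationError("config must provide either 'simulation' or 'inputs'")
    return cfg
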