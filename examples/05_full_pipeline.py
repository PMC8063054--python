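"""Run the whole validation pipeline from a single config.

One call generates the synthetic two-study dataset, runs normalization,
batch removal, embedding, the signature cascade, the presence Venn,
differential expression and the qPCR readout, writes every artifact to
an output directory, and returns a machine-readable summary.  The same
config and seed always produce a byte-identical summary.json.
"""

import json

from imglia import run_pipeline

config = {
    "seed": 7,
    "simulation": {"n_genes": 1200, "n_signature": 120},
    "stages": {"embedding": {"k": 2}},
    "qpcr": {
        "simulation": {
            "n_replicates": 3,
            "target_delta_ct": {"control": 5.0, "LPS": 2.0},
            "noise_sd": 0.3,
        },
        "treated": "LPS",
        "control": "control",
    },
}

summary = run_pipeline(config, output_dir="pipeline_demo")
print(json.dumps(summary, indent=2, sort_keys=True))
print("\n-> cascade_stage_counts shrink monotonically after the union stage;")
print("   cluster_purity 1.0 and img_nearest_reference_centroid ref_microglia")
print("   are the identity-validation result; rerunning with the same seed")
print("   reproduces pipeline_demo/summary.json byte for byte.")
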