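"""Run the whole chain from one config: simulate -> normalize -> fit ->
assign -> associate -> clinical, into an auditable results directory.

Equivalent CLI:  substage run-all --config <yaml> --out results/demo
"""

from substage import RunConfig, run_pipeline
from substage import io as sio

cfg = RunConfig.model_validate({
    "seed": 5,
    "output_dir": "results/demo",
    "cohort": {
        "n_controls": 80, "n_patients": 80, "n_subtypes": 2,
        "opposed_sequences": True, "n_regions": 12,
        "planted_edges": [{"i": 1, "j": 7, "rho": 0.7, "subtype": 1}],
        "clinical_slopes": {"hostility": [0.735, 0.0]},
    },
    "sustain": {"z_thresholds": [1.0, 2.0], "max_subtypes": 2,
                "n_restarts": 3, "em_iters": 8, "split_restarts": 2},
    "association": {"n_permutations": 2000, "min_subtype_n": 8},
})

out = run_pipeline(cfg, overwrite=True)
summary = sio.read_yaml(out / "summary.yaml")
print("results in:", out)
print("selected number of subtypes:", summary["selected_n_subtypes"])
for row in summary["bic_table"]:
    print(f"  C={row['n_subtypes']}  logL={row['log_likelihood']:.1f}  "
          f"BIC={row['bic']:.1f}")
meta = sio.read_yaml(out / "association_meta.yaml")
for c, info in meta["subtypes"].items():
    print(f"fitted subtype {c}: n={info['n']}, FWER-significant edges: "
          f"{info['edge_fwer_hits']}")

# fitted subtype labels are arbitrary, so look the planted edge up in both scans
for c in meta["subtypes"]:
    scan = sio.read_csv(out / f"assoc_edges_subtype{c}.csv")
    row = scan[scan.unit == "roi_001--roi_007"].iloc[0]
    print(f"planted edge in fitted subtype {c}: rho={row.rho:+.2f} "
          f"p_fwer={row.p_fwer:.4f}")
print("\nBIC should pick the 2 planted subtypes; in whichever fitted label "
      "holds the planted-effect patients, the roi_001--roi_007 edge should "
      "approach its planted rho=0.7 and reach FWER significance, while the "
      "other label sees only noise.  Every artefact in the directory is "
      "reproducible from the config and seed.")
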