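"""Full pipeline round trip on a synthetic input bundle.

Simulates a small bundle (PDB structures, a stability CSV, mutation and
gene-role tables), then runs every analysis stage over it and lists the
output tables. The same flow is available from the shell as
`oncostruct simulate` / `oncostruct run` / `oncostruct report`.
"""

import tempfile
from pathlib import Path

import pandas as pd

from oncostruct import RunConfig, run_pipeline, simulate_bundle

with tempfile.TemporaryDirectory() as tmp:
    bundle_dir = Path(tmp) / "bundle"
    paths = simulate_bundle(
        RunConfig(output_dir=str(bundle_dir), n_genes=4, n_residues=60, seed=5)
    )
    config = RunConfig(
        structures_dir=str(paths["structures"]),
        stability_csv=str(paths["stability"]),
        mutations_tsv=str(paths["mutations"]),
        roles_tsv=str(paths["roles"]),
        output_dir=str(Path(tmp) / "out"),
        sasa_points=240,
    )
    outputs = run_pipeline(config)

    print("output tables:")
    for name, path in outputs.items():
        print(f"  {name:18s} {path.name}")

    volcano = pd.read_csv(outputs["volcano"], sep="\t", comment="#")
    print("\nvolcano (gene-level damage enrichment):")
    print(volcano.to_string(index=False))
    print("\npositive ddg_rank_diff rows are candidates for TSG-like behaviour")
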