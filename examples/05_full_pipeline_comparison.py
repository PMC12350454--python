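"""The full comparative workflow on two synthetic systems.

Generates a "mutant" (state-dependent decorrelation switched on) and a
"wild-type" fixture, runs the complete chain — stability, CVs, landscape,
crucial interval, DCCM, MM/GBSA, decomposition, interactions — and
prints the comparison report. Outputs land in ./pipeline_demo_out/.
"""

import json
import tempfile
from pathlib import Path

from bindscape import RunConfig, SystemConfig, run_pipeline
from bindscape.synthetic import ToySpec, write_fixture_set

workdir = Path(tempfile.mkdtemp(prefix="bindscape_demo_"))
out_dir = Path("pipeline_demo_out")

systems = []
for name, seed, coupling in (("mutant", 31, 0.7), ("wildtype", 32, 0.0)):
    spec = ToySpec(seed=seed, n_frames=800, coupling=coupling)
    write_fixture_set(workdir, [(name, "two_basin", spec)])
    anchor = spec.n_residues // 2 + 1
    systems.append(SystemConfig(
        name=name,
        topology_pdb=str(workdir / f"{name}.pdb"),
        topology_json=str(workdir / f"{name}.topology.json"),
        trajectories=[str(workdir / f"{name}.dcd")],
        cv_residue_selection=f"resid:{anchor} AND segment:protein",
        # keep the "pocket" region inside one coherent block of the
        # generator so its internal correlation is interpretable
        region_p=list(range(anchor, anchor + 6)),
        region_c=list(range(spec.n_residues - 5, spec.n_residues + 1)),
    ))

config = RunConfig(systems=systems, output_dir=str(out_dir), seed=1,
                   window_frames=100)
manifest = run_pipeline(config)
print(f"pipeline complete: {manifest['complete']}")
print(f"stages run       : {len(manifest['stages'])}")

comparison = json.loads((out_dir / "comparison.json").read_text())
for label, d in comparison["delta_region_correlation"].items():
    print(f"{label} internal correlation: mutant {d['mean_a']:+.3f} "
          f"vs wild-type {d['mean_b']:+.3f} (delta {d['delta_mean']:+.3f})")
print(f"delta binding total: {comparison['delta_binding_total']:+.3f} kcal/mol")
# The DCCM here is computed over the crucial interval — ground-basin
# frames, where the mutant's state-dependent decorrelation (active only
# in the second basin) barely acts — so near-zero deltas are expected;
# rerun dccm over the whole trajectory to expose the decoupling. Every
# table behind these numbers is in pipeline_demo_out/.
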