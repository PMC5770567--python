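"""Full pipeline: simulate, analyse, and classify the phase state.

Runs the whole chain — tessellation, ordered-cluster detection,
registration, correlations, persistence — on a demixed and a mixed
synthetic trajectory, and prints the verdict with its evidence.
"""

import json

from nanodomain import run_pipeline

CONFIGS = {
    "demixed": {"source": {"kind": "synthetic", "lattice_side": 28,
                           "coupling": 1.1, "interleaflet_coupling": 1.0,
                           "sweeps": 2000, "n_frames": 8,
                           "sweeps_per_frame": 80},
                "analysis": {"analysis_fraction": 0.25, "bin_width": 0.2}},
    "mixed": {"source": {"kind": "synthetic", "lattice_side": 28,
                         "coupling": 0.2, "interleaflet_coupling": 0.0,
                         "sweeps": 500, "n_frames": 8,
                         "sweeps_per_frame": 120},
              "analysis": {"analysis_fraction": 0.25, "bin_width": 0.2}},
}

for name, config in CONFIGS.items():
    bundle = run_pipeline(config, seed=5, outdir=f"scratch/pipeline_{name}")
    summary = bundle["summary"]
    evidence = bundle["verdict"]["evidence"]
    print(f"--- {name} trajectory ---")
    print(f"phase verdict        {summary['phase']}")
    print(f"long-range decay     {evidence['long_range']}")
    print(f"interleaflet overlap {evidence['overlap']:.3f}")
    print(f"persistence          {evidence['persistence']:.3f}")
    print(f"A_L ordered/disord   {summary['A_L_ordered']:.3f} / "
          f"{summary['A_L_disord']:.3f} nm^2")
    print(f"C_sat in ordered     {summary['C_i']['sat']:.2f}")
    print()

print("two_phase requires long-range decay AND overlap > 0.7 AND a "
      "persistent\ndensity pattern; a mixed state fails all three and is "
      "labelled one_phase.")
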