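"""Reproducible study campaigns via the scenario manifest.

The manifest enumerates the whole simulation matrix — {cuboid, spherical}
phantoms x tissue depths 0-10 cm x {symmetric, asymmetric} plans, plus
full-scatter references and steel-cable variants — with per-scenario seeds
derived deterministically from one master seed.  Here we build it, run a
small filtered subset at reduced scale, and print the resulting tallies
and DMFs.
"""

import numpy as np

from brachydmf import Plan, build_manifest, run_manifest

manifest = build_manifest(master_seed=42, scale=0.004)  # 2e5 histories/run
print(f"manifest: {len(manifest.records)} scenarios "
      f"({len(manifest.finite_records)} finite-depth records)")

subset = ["spherical_d00_symmetric", "spherical_d05_symmetric",
          "ref_symmetric"]
plans = {
    "symmetric": Plan(
        weights=np.ones(35),
        active_lumens=("central", "A", "B", "C", "D"),
        normalization=1.0,
        label="symmetric",
    )
}
tallies, dmf = run_manifest(manifest, ids=subset, plans=plans, log=None)

print("\ntallies (dose per source photon at the reference point):")
print(tallies[["scenario", "dose_per_history", "rse"]].to_string(index=False))
print("\nDMF rows (full-scatter reference / finite-depth tally):")
print(dmf[["phantom", "depth_cm", "dmf", "underdose_percent"]]
      .to_string(index=False))
print(
    "\nRe-running with the same master seed reproduces these numbers"
    " bit for bit; at this reduced scale each DMF carries several percent"
    " of statistical noise."
)
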