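"""Does the steel source cable matter for the backscatter analysis?

Runs paired wire-on / wire-off simulations with common random numbers (the
same per-history streams), so the sub-percent perturbation of the DMF by
the cable is resolved far below single-run statistical noise.
"""

import numpy as np

from brachydmf import EngineConfig, WireSpec, build_applicator, wire_effect

applicator = build_applicator()
result = wire_effect(
    plan=np.ones(35),
    phantom_kind="cuboid",
    depths=[0.0, 5.0],
    wire=WireSpec(radius=0.045),  # type-304 steel, default cable radius
    config=EngineConfig(n_histories=2_000_000, seed=3),
    applicator=applicator,
)

print("change in DMF from adding the steel cable (paired seeds)")
print("depth_cm   dDMF         sigma")
for d, diff, sig in zip(result.depths, result.difference, result.sigma):
    print(f"{d:8.1f}   {diff:+.5f}   {sig:.5f}")
print(
    f"\nmax |dDMF| = {result.max_abs_difference:.5f} — well under 1%: the"
    " cable attenuates a few percent of the absolute dose, but the DMF is a"
    " ratio to the full-scatter reference and almost all of it cancels, so"
    " the backscatter study can neglect the cable."
)
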