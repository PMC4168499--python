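"""Multivariate multiscale entropy of a relaxed vs a stressed recording.

Generates one synthetic recording per class (five channels, 2700 samples
at 4 Hz) and prints the MSampEn value at each coarse-graining scale 1..9.
The relaxed recording keeps its complexity at coarse scales (1/f-like
dynamics); the stressed one loses it (regular paced dynamics).
"""

from physiofuse import SimulationSpec, generate_recording, mmse_profile

spec = SimulationSpec(seed=1, complexity_gap=0.8)
relaxed = generate_recording(spec, "Relaxed", 0)
stressed = generate_recording(spec, "Stressed", 0)

p_relaxed = mmse_profile(relaxed)
p_stressed = mmse_profile(stressed)

print("scale  n_eff   MSampEn(Relaxed)  MSampEn(Stressed)")
for scale, n_eff, vr, vs in zip(
    p_relaxed.scales, p_relaxed.n_effective, p_relaxed.values, p_stressed.values
):
    print(f"{scale:>5}  {n_eff:>5}   {vr:>16.4f}  {vs:>17.4f}")

print(
    f"\nAt the coarsest scale the relaxed recording is the more complex one "
    f"({p_relaxed.values[-1]:.3f} vs {p_stressed.values[-1]:.3f}): the "
    f"complexity-loss signature that separates the two regimes."
)
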