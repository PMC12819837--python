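"""Swap the operator into a ResNet-18 and account for the cost.

Builds the four classifier variants (baseline and one per branch
combination), replacing the first 3x3 convolution of each of the eight
BasicBlocks, and prints parameters and multiply-accumulates with deltas
versus the baseline.  The edge branch (MEFE) *shrinks* the network —
its pyramid works on channel-reduced, pooled maps — while the attention
branch adds a little and the fused operator adds the most.
"""

from seafec import SurgeryPlan, build_seafec_resnet18, compare

models = {
    v: build_seafec_resnet18(SurgeryPlan("resnet18", v, num_classes=1000))
    for v in ("baseline", "scarf", "mefe", "seafec")
}
reports = compare(models, baseline="baseline", input_shape=(3, 64, 64))

print(f"{'variant':<10} {'params(M)':>10} {'dParams%':>9} {'MACs@64(M)':>11} {'dMACs%':>8}")
for name, rep in reports.items():
    dp = f"{rep.delta_params_pct:+.1f}" if rep.delta_params_pct is not None else "-"
    dm = f"{rep.delta_macs_pct:+.1f}" if rep.delta_macs_pct is not None else "-"
    print(f"{name:<10} {rep.params_m:>10.2f} {dp:>9} {rep.macs / 1e6:>11.1f} {dm:>8}")
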