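"""Track OTFRM across training stages.

Emulates the three snapshots of a representation's life — randomly
initialized (tasks fully mixed), pretrained (partly organized), and
fine-tuned (tight separated clusters) — with cluster separations
0 / 1 / 4 in units of the within-task spread, and shows each task's
OTFRM rising through the stages.  PT/RI and FT/PT are the stage-over-
stage ratios: how much each learning step improved that task's
feature-space organization.
"""

from otfrm import SyntheticSpaceSpec, generate_stage_snapshots, stage_comparison

spec = SyntheticSpaceSpec(K=6, m=50, d=16, sigma=1.0, seed=5)
snaps = generate_stage_snapshots(spec, deltas=(0.0, 1.0, 4.0))
comparison = stage_comparison(snaps)

print(f"{'task':8s} {'RI':>8s} {'PT':>8s} {'FT':>8s} {'PT/RI':>8s} {'FT/PT':>8s}")
for tid, e in comparison.per_task.items():
    print(
        f"{tid:8s} {e['otfrm_RI']:8.4f} {e['otfrm_PT']:8.4f} {e['otfrm_FT']:8.4f}"
        f" {e['ratio_PT_over_RI']:8.4f} {e['ratio_FT_over_PT']:8.4f}"
    )
print("(ratios > 1: the task benefited from that training stage)")
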