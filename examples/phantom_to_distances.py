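"""Full geometric pipeline on one synthetic bone pair with known truth.

Builds a phantom tibia scanned by two protocols (0.30x0.30x0.60 mm vs
0.49x0.49x0.625 mm voxels) whose second model is systematically 0.20 mm
smaller and rigidly misaligned, then runs mesh extraction, trimmed ICP,
FROI clipping and signed distances.  The recovered mean should land near
the true +0.20 mm offset, and the recovered pose near the true one.
"""

import numpy as np

from bonequiv import PhantomSpec, RigidTransform, compare_bone_pair
from bonequiv.phantom import make_pair

truth_pose = RigidTransform.from_axis_angle((0.2, 1.0, 0.1), angle_deg=3.0, translation=(1.5, -0.5, 2.0))
spec = PhantomSpec(bone="tibia", size=26.0, delta=0.20, sigma_noise=0.1, transform=truth_pose, seed=42)
pair = make_pair(spec)
print(f"grid A: {pair.grid_a.data.shape} voxels at {pair.grid_a.spacing} mm")
print(f"grid B: {pair.grid_b.data.shape} voxels at {pair.grid_b.spacing} mm")

result = compare_bone_pair(pair.grid_a, pair.grid_b, bone="tibia")
pose_err = result.transform.compose(pair.truth.transform.inverse())
s = result.summary
print(f"\nICP converged in {len(result.rms_trace)} iterations")
print(f"pose error vs ground truth: {pose_err.rotation_angle_deg:.2f} deg, "
      f"{np.linalg.norm(pose_err.translation):.3f} mm")
print(f"signed A->B distances over {s.n} FROI vertices:")
print(f"  mean {s.mean:+.3f} mm (true offset {spec.delta:+.2f}), std {s.std:.3f} mm")
print(f"  population interval [{s.lower:+.2f}, {s.upper:+.2f}] mm")
print("\npositive mean = the first modality's model is larger, as constructed")
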