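#!/usr/bin/env python
"""Build the synthetic head phantom and check its geometric calibration.

Constructs the default layered phantom (ellipsoidal scalp, skull and
parasagittal tumor), writes the layer meshes and the voxel label volume
under results/phantom/, and verifies the two calibration facts everything
downstream depends on: the projected tumor silhouette area (reference
2,717 mm²) and the voxel/marching-cubes reconstruction of the tumor.
"""

import sys
from pathlib import Path

import numpy as np

from neuroplan import io as npio
from neuroplan import phantom as ph
from neuroplan.pipeline import build_phantom_artifacts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    model = build_phantom_artifacts(OUT / "phantom")
    sil = model.silhouette()
    ref = ph.REFERENCE_TUMOR_AREA
    print(f"tumor silhouette area: {sil.area:.1f} mm² (closed form {ref:.1f}, "
          f"relative error {abs(sil.area - ref) / ref:.2%})")

    spec = model.spec
    vol = npio.read_volume(OUT / "phantom" / "labels.nii.gz")
    analytic = 4 / 3 * np.pi * np.prod(spec.tumor_semiaxes)
    est = vol.volume_of(ph.LABELS["tumor"])
    print(f"tumor volume from voxels at {vol.pitch} mm pitch: {est:.0f} mm³ "
          f"(ellipsoid {analytic:.0f} mm³, error {abs(est - analytic) / analytic:.2%})")

    mesh = ph.extract_surface(vol, ph.LABELS["tumor"])
    print(f"marching-cubes tumor surface: watertight={mesh.is_watertight}, "
          f"enclosed volume {mesh.volume:.0f} mm³")
    print(f"phantom artifacts in {OUT / 'phantom'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
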