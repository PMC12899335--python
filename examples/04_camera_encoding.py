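"""Project a simulated trajectory into a fixed upward-looking camera and
render one sky frame with the target drawn at its apparent size.

At surveillance ranges the target spans only a few pixels, which is why
the classifier works from motion rather than appearance.
"""

import math
import tempfile
from pathlib import Path

import numpy as np

import skytrace as st
from skytrace.camera import CameraModel, encode_image_plane_track, random_sky, \
    render_frame, write_png

cam = CameraModel.from_fov(math.radians(70), 640, 480)
print(f"camera: f = {cam.fx:.1f} px for a 70 deg field of view at 640 px")

rec = st.simulate_trajectory("bird", "pigeon", T=30.0, dt=0.03, seed=8)
track = encode_image_plane_track(cam, rec, l_phys=0.6)
visible = np.isfinite(track[:, 0])
print(f"{visible.sum()} of {len(track)} frames project in front of the camera")
sizes = track[visible, 2]
print(f"apparent size: median {np.median(sizes):.1f} px "
      f"(a 0.6 m bird at ~{np.median(rec.positions[:, 2]):.0f} m altitude)")

sky = random_sky(np.random.default_rng(0), 640, 480)
i = int(np.nonzero(visible)[0][0])
img = render_frame(cam, sky, t=i * rec.dt, targets=[(rec.positions[i], 0.6)])
out = Path(tempfile.gettempdir()) / "skytrace_frame.png"
write_png(img, out)
print(f"rendered one frame (sky gradient + drifting clouds + target) to {out}")
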