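#!/usr/bin/env python
"""Patch-to-nanoparticle SASA scale-up and pocket accommodation check.

Two desk-scale calculations: (1) scaling a per-patch SASA difference of
63 nm^2 (a ~10 x 10 nm monolayer patch) to a 10 nm-radius spherical
nanoparticle, compared against the IgV-like domain surface of 75 nm^2;
(2) verifying that a constructed 4 nm-deep, 3 nm-wide well is detected by
the height-map pocket finder and flagged as able to host the IgV-proxy
probe, while a flat surface is not.  Writes results/scaleup_pockets.json.
"""
import json
import sys
from pathlib import Path

import numpy as np

from sambrush.io import AtomRecord, Frame, Moiety, Topology
from sambrush.surface import accommodates_probe, height_map, scale_patch_to_sphere

ROOT = Path(__file__).resolve().parents[1]


def carved_well_frame(depth=4.0, width=3.0, box=(10.0, 10.0, 12.0)):
    spacing, vdw, z_top = 0.15, 0.1, 5.0
    xs = np.arange(spacing / 2, box[0], spacing)
    gx, gy = np.meshgrid(xs, xs)
    pos = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z_top)])
    r = np.linalg.norm(pos[:, :2] - [box[0] / 2, box[1] / 2], axis=1)
    pos[r < width / 2, 2] = z_top - depth
    topo = Topology([
        AtomRecord(i, "CA", "C", "ALA", i + 1, 0, Moiety.PEPTIDE, 100.0, vdw,
                   is_calpha=True)
        for i in range(len(pos))
    ])
    return Frame(pos, box), topo


def main() -> None:
    patch = 10.32 * 9.99
    scaled = scale_patch_to_sphere(63.0, patch, 10.0)
    ratio = scaled / 75.0
    print(f"63 nm^2 per {patch:.1f} nm^2 patch on a 10 nm sphere -> {scaled:.0f} nm^2")
    print(f"ratio to the 75 nm^2 IgV-like surface: {ratio:.1f}x")

    frame, topo = carved_well_frame()
    hm = height_map(frame, topo, np.arange(len(topo)), grid_resolution=0.2)
    ok, hits = accommodates_probe(hm)
    p = hm.pockets[0]
    print(f"carved well: depth {p.depth:.2f} nm, width {p.width:.2f} nm, "
          f"accommodates probe: {ok}")

    flat = np.full(len(topo), 5.0)
    flat_frame = Frame(np.column_stack([frame.positions[:, :2], flat]), frame.box)
    hm_flat = height_map(flat_frame, topo, np.arange(len(topo)), grid_resolution=0.2)
    ok_flat, _ = accommodates_probe(hm_flat)
    print(f"flat surface accommodates probe: {ok_flat}")

    out = ROOT / "results" / "scaleup_pockets.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps({
        "scaled_sasa_nm2": scaled, "igv_ratio": ratio,
        "well_depth_nm": p.depth, "well_width_nm": p.width,
        "well_accommodates": ok, "flat_accommodates": ok_flat,
    }, indent=2))
    print(f"\nWrote {out}")


if __name__ == "__main__":
    sys.exit(main())
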