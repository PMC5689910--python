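# JSON contour dialect

A plain-text structure-set format mirroring the DICOM-RT Structure Set
content model (named, coloured stacks of closed planar contours), used so
that fixtures and exchange files need no binary DICOM.

All coordinates are millimetres in the same frame of reference as the
referenced image volumes.

```json
{
  "frame_of_reference": "1.2.826.0.1.3680043.10.424.1",
  "structures": [
    {
      "name": "itv",
      "color": [1.0, 1.0, 0.0, 1.0],
      "role": "target",
      "bins": [
        [
          {"z": -6.0, "points": [[12.0, 3.0], [18.0, 3.0], [18.0, 9.0], [12.0, 9.0]]},
          {"z": -3.0, "points": [[11.0, 2.0], [19.0, 2.0], [19.0, 10.0], [11.0, 10.0]]}
        ]
      ]
    }
  ]
}
```

* `frame_of_reference` — free text; written to DICOM-RTSS as the
  FrameOfReferenceUID, so keep it UID-shaped if round-tripping to DICOM.
* `structures[].name` — unique structure name.
* `structures[].color` — RGBA in [0, 1].
* `structures[].role` — `target`, `oar` or `margin`.
* `structures[].bins` — one list of contours per time bin (static
  structures have a single bin). Each contour is a closed planar polygon:
  `z` is the axial slab position (mm) and `points` the ordered `[x, y]`
  vertices (implicitly closed, ≥ 3 vertices, non-self-intersecting).

Nested contours on one slice are interpreted by the even-odd rule
(holes). DICOM-RTSS export writes bin 0 only, as CLOSED_PLANAR contours.
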