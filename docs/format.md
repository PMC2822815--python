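# The `.sgx` exam archive format

A cardioflow exam archive stores a complete analysis — image stacks,
contours, measurements and annotation points — so one can later go back
and see exactly how delineations were made. Version `1.0`.

## Container

A standard zip file containing:

- `manifest.json` — all metadata and small objects (UTF-8 JSON)
- `stack_<i>.f8` — one raw binary blob per image stack: the voxel array
  in little-endian IEEE-754 float64 (`<f8`), C order, with the shape
  recorded in the manifest

Everything except the voxel blobs is plain JSON, so archives are
inspectable with `unzip -p exam.sgx manifest.json | python -m json.tool`.

## Manifest schema

```json
{
  "format": "cardioflow-exam",
  "version": "1.0",
  "stacks": [
    {
      "blob": "stack_0.f8",
      "dtype": "<f8",
      "shape": [rows, cols, slices, frames],
      "pixel_spacing_mm": [row, col],
      "slice_thickness_mm": 8.0,
      "slice_gap_mm": 0.0,
      "time_increment_s": 0.05,
      "image_type": "magnitude | phase | ct",
      "venc_cm_s": null,
      "origin_mm": [x, y, z],
      "row_dir": [x, y, z],
      "col_dir": [x, y, z],
      "series_uid": "...",
      "stored_bits": 12
    }
  ],
  "contours": [
    {"label": "...", "slice": 0, "frame": 0, "vertices": [[x, y], ...]}
  ],
  "measurements": {"column name": [values, ...]},
  "annotations": [
    {"position": [x, y, slice], "frame": null, "label": "..."}
  ]
}
```

Contour vertices and annotation positions are stored as JSON numbers at
full double precision (no rounding is applied on write). Voxel blobs
round-trip bit-for-bit.

## Versioning and integrity

Readers must refuse archives whose `version` they do not support, and
must verify zip CRC integrity before trusting contents; truncated files
are reported as integrity errors, not partially loaded.
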