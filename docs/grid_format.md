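# Grid file format

A minidock grid file stores one scalar lattice: a seven-line text header
followed by the values.  Files may be gzipped (`.grid.gz`); reading is
transparent.  Grid extents live entirely in the header — consumers allocate
dynamically, so changing grid sizes never requires reconfiguration.

```
# minidock grid 1
kind <vdw_repulsive|vdw_attractive|electrostatic|desolvation|generic>
units <free text, '-' if none>
origin <x> <y> <z>          (A; position of lattice point (0,0,0))
spacing <s>                 (A; uniform in all three axes)
dims <nx> <ny> <nz>
encoding <text|binary>
```

Then `nx*ny*nz` values in **x-fastest** order (x varies quickest, then y,
then z):

* `text` — one value per line, full double precision (`%.17g`, so the
  round trip is exact);
* `binary` — raw little-endian float64, immediately after the header's
  final newline.

Grid kinds and units as used by the scoring bundle:

| kind            | meaning                                   | units               |
|-----------------|-------------------------------------------|---------------------|
| vdw_repulsive   | sum over receptor atoms of sqrt(A)/r^12   | sqrt(kcal/mol)/A^12 sums |
| vdw_attractive  | sum of sqrt(B)/r^6                        | sqrt(kcal/mol)/A^6 sums  |
| electrostatic   | electrostatic potential                   | kcal/(mol e)        |
| desolvation     | fractional desolvation                    | dimensionless (0-1) |

A scoring bundle is a directory holding the four files
`vdw_repulsive.grid`, `vdw_attractive.grid`, `electrostatic.grid`,
`desolvation.grid`, all sharing one lattice.  Electrostatic grids produced in
other unit systems can be imported with the bundle's scale factor
(`GridBundle(electrostatic_scale=...)`).
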