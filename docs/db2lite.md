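# The db2-lite hierarchy format

`db2-lite` is minidock's documented text dialect for flexibase hierarchies: a
molecule's atoms, bonds, charges and per-atom desolvation terms, its rigid
component, and one coordinate block plus builder energy per conformer.  It
carries the same content as production flexibase files but is deliberately a
simple line-oriented format, human-readable and trivially parsed in any
language.  Files may be gzip-compressed (`.db2.gz`); reading is transparent.

One file may hold any number of records, concatenated.

## Record layout

```
db2lite 1
name <molecule name>
counts <n_atoms> <n_bonds> <n_conformers>
atom <index> <name> <element> <mol2_type> <charge> <vdw_class> <desolvation>
...                                 (one line per atom, 0-based indices)
bond <i> <j> <order>                (order: 1, 2, 3, am, ar)
...
rigid <i1> <i2> ...                 (atom indices of the rigid component)
conf <k> <energy>                   (k: conformer index; energy: kcal/mol)
coord <x> <y> <z>                   (n_atoms lines, Angstroms, atom order)
...                                 (repeat conf/coord per conformer)
end
```

* `charge` is the partial atomic charge in electron units.
* `desolvation` is the per-atom transfer free energy (kcal/mol) multiplied
  into the receptor's fractional-desolvation grid at scoring time.
* `vdw_class` keys into the van der Waals parameter table (it usually equals
  the mol2 type).
* Blank lines and `#` comments are ignored.

## Validation on read

Every conformer must be a complete input conformation sharing the rigid
component: the rigid-component coordinates of each conformer must agree with
conformer 0 within 1e-3 A (directly or after least-squares superposition).
A record violating this is rejected.  `counts` must match the parsed
entities.

## Worked example

A two-atom, one-conformer record (methanol-fragment-sized, purely
illustrative):

```
db2lite 1
name tiny
counts 2 1 1
atom 0 C1 C C.3 -0.100000 C.3 0.200000
atom 1 O1 O O.3 0.100000 O.3 0.300000
bond 0 1 1
rigid 0 1
conf 0 1.500000
coord 0.000000 0.000000 0.000000
coord 1.400000 0.000000 0.000000
end
```

Parsing yields two atoms (a carbon at the origin, an oxygen 1.4 A along x,
charges -0.1/+0.1 e), one single bond, and one conformer whose builder energy
is 1.5 kcal/mol.  Note a molecule this small is not dockable (matching needs
at least 4 rigid heavy atoms); it round-trips through the format regardless.
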