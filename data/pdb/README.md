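# Deposited coordinate files for real-structure validation

The deposited-structure tests in `tests/test_acceptance.py` reproduce
numbers measured on real S. aureus FtsZ crystal structures.  Those
entries are not redistributed here; fetch them into this directory
yourself (any of `.pdb`, `.cif`, `.ent` is accepted):

```sh
cd data/pdb
for id in 3VOA 3VO8 3VOB 4DXD 3WGK 3WGL 3WGN 5MN4 5MN5 5MN6 5MN7 5MN8; do
    wget https://files.rcsb.org/download/$id.pdb
done
```

Two small JSON files must also be provided:

* `mapping.json` — the validation tests refer to the five deposited
  mutant structures by their descriptive names 1FOf, 2TCm, 3FCm, 4FCs
  and 5FCm (number, mutation F/T, conformation O/C, packing f/m/s);
  the pairing with deposition ids (5MN4–5MN8) is not fixed a priori,
  so check the deposition titles and supply it, e.g.:

  ```json
  {"1FOf": "5MN4", "2TCm": "5MN5", "3FCm": "5MN6", "4FCs": "5MN7", "5FCm": "5MN8"}
  ```

* `operators.json` — crystallographic symmetry operators that generate
  the longitudinal neighbor of chain A in the filament-containing
  lattices (this package deliberately does not expand space groups;
  one explicit operator per entry is all a protofilament neighbor
  needs).  Format:

  ```json
  {"3VOA": {"rotation": [[1,0,0],[0,1,0],[0,0,1]], "translation": [0.0, 0.0, 44.0]},
   "3WGL": {"rotation": [[1,0,0],[0,1,0],[0,0,1]], "translation": [0.0, 0.0, 45.0]}}
  ```

  The operator is read from the entry's symmetry records (in
  orthogonal Å coordinates) for the neighbor contact along the
  filament axis.

Everything else in the test suite runs without any of these files.
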