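# Empirical multiplex datasets (optional)

The empirical checks in `tests/test_acceptance.py` run only when the two
published multiplex social networks are present here as plain-text edge
lists in the default `layer u v` dialect (one edge per row; an optional
fourth weight column is binarised):

* `terrorists.edges` — the Indonesian-terrorists multiplex: 78 individuals,
  3 layers (trust, common operations, communication); structural overlap
  ~0.48.
* `auger.edges` — the Pierre Auger observatory collaboration multiplex:
  16 task layers; the giant component of its aggregate has 475 members and
  structural overlap ~0.069.

Both datasets are distributed by their original publishers (CoMuNe-lab /
Manlio De Domenico's multiplex network collection); convert the released
layer edge lists to the three-column format above.  Without these files
the corresponding test is skipped; everything else in the package is
validated on synthetic ensembles.
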