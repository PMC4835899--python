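# Real-structure validation inputs

`tests/test_acceptance.py::test_real_structure_validation` checks
classification anchors on deposited structures.  It expects the PDB
entries below as plain PDB files in this directory (lowercase names):

    2zdp.pdb   IsdI, homodimeric Type-1 barrel, proximal His76
    3a16.pdb   aldoxime dehydratase, fused Type-2 barrel, proximal His299
    3nn1.pdb   chlorite dismutase, fused Type-1 barrel

They are not redistributed with this repository; download them from the
Protein Data Bank (https://files.rcsb.org/download/XXXX.pdb).  Without
these files the test reports the missing inputs and fails.
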