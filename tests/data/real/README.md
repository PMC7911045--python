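# Real-structure check data

The fold-retention acceptance test superposes the evolved variant structure
(PDB entry **7AVC**) onto its parent scaffold (PDB entry **4PSF**, human PIH1
domain-containing protein 1) and expects a Cα RMSD of about 0.93 Å over about
129 common Cα atoms.

These coordinate files are not redistributed with the package. To run the
check, download them into this directory:

```sh
curl -o tests/data/real/4psf.pdb https://files.rcsb.org/download/4PSF.pdb
curl -o tests/data/real/7avc.pdb https://files.rcsb.org/download/7AVC.pdb
```

Without network access the test fails with a pointer to this file; every other
test runs on synthetic data generated by `scaffoldsmith.fixtures`.
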