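# Reference coordinates (user-supplied)

The two crystal-comparison tests in `tests/test_acceptance.py` superpose the
deposited Tpm3.1 N-terminal crystal structure onto two published reference
structures.  Deposited coordinates are not redistributed with this package;
to run those tests, download the entries from the Protein Data Bank
(https://www.rcsb.org), save them in legacy PDB format, and place them here
as:

- `6otn.pdb`   - Tpm3.1 N-terminal fragment crystal structure
- `1ic2.pdb`   - Tpm1.1 N-terminal fragment crystal structure
- `tm1bzip.pdb` - the alphaTM1bZip chimera crystal structure (N-terminal
  tropomyosin residues fused to the GCN4 leucine zipper)

Without these files the two tests fail with a message pointing back to this
directory; every other test is self-contained.
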