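Drop accession coordinate files here (e.g. 2JK2.pdb, 2VOM.pdb) to make the
accession-based regression tests and scripts/acceptance.py runnable offline.
wetcore.datasets also checks $WETCORE_PDB_DIR and ./data/pdb, and downloads
from RCSB when the network allows.
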