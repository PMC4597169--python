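# SYNTHETIC default contact map: HLA class I groove residues contacting each
# peptide position of a 9-mer ligand.
#
# This is a reconstruction assembled from the classical pocket (A-F)
# assignments of the class I binding-groove literature, NOT a measured or
# authoritative list.  Residue numbers are 1-based on the mature chain of
# A*02:01 (PDB 3HLA numbering) and must lie within the gapless aligned region
# (residues 2-182).  Edit or replace this file to substitute other contact
# definitions (e.g. the NetMHCpan pseudo-sequence positions).
#
# peptide_position: [HLA residue numbers]
1: [5, 7, 59, 63, 66, 99, 159, 163, 167, 171]
2: [7, 9, 24, 25, 34, 45, 63, 66, 67, 70, 99]
3: [99, 113, 114, 152, 155, 156, 159]
4: [62, 65, 66, 69, 155, 159, 163]
5: [69, 70, 73, 97, 114, 155, 156]
6: [9, 70, 73, 74, 97, 114]
7: [97, 114, 147, 150, 152, 156]
8: [72, 73, 76, 80, 143, 146, 147]
9: [77, 80, 81, 84, 95, 116, 118, 123, 143, 146, 147]
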