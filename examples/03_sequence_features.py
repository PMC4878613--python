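"""Scan a transcript sequence for canonical ORFs and its pseudo-5'UTR.

The pseudo-5'UTR is the distance from the transcript 5' end to the first
AUG of its 5'-most open reading frame; in real data, polysomal lncRNAs
carry longer, more mRNA-like leaders than free cytoplasmic ones.
"""

from polysomeloc import seqfeat

seq = ("GGCAUCCGUAAGGCAUGGCUAAAGCUUUGCCCAUGACGUAAGGAUCCGGAAUGCCC"
       "UUAAGGCGCGAUAGCUAAGCUAGCUGA")

print(f"sequence ({len(seq)} nt): {seq}")
print(f"pseudo-5'UTR length: {seqfeat.pseudo_five_utr(seq)} nt")
print(f"GC content: {seqfeat.gc_content(seq):.2f}")
print(f"total ORF coverage: {seqfeat.total_orf_coverage(seq):.2f} "
      "(fraction of bases inside any six-frame ORF)")
print("ORFs (frames 0-2 forward, 3-5 on the reverse complement):")
for orf in seqfeat.scan_orfs(seq):
    print(f"  frame {orf.frame}: start {orf.start:3d}  end {orf.end:3d}  "
          f"length {orf.length} nt")
print("Per stop codon only the 5'-most in-frame start is reported: nested")
print("AUGs inside a longer ORF are suppressed.")
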