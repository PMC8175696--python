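"""Classify RNase-T2 family members into S-RNase candidates and find the
S-locus on a synthetic annotation.

Candidates must lack amino-acid pattern 4 and have an isoelectric point
in [8, 10]; an S-locus candidate is an S-RNase gene with F-box genes in
its flanking region.
"""

from wgtkit import classify, find_slocus
from wgtkit.io import GeneFeature

proteome = {
    # motif-bearing (CPQDAD at the start): an ordinary RNase-T2
    "rnase_class1": "CPQDAD" + "AGSTNQ" * 20,
    # motif-free and moderately basic: the S-RNase profile
    "srnase_like": "KKKKDD" + "AILMNQSTVW" * 5,
    # motif-free but acidic: fails the pI band
    "rnase_acidic": "DDEEDD" + "AILMNQSTVW" * 5,
}

verdicts = classify(proteome, list(proteome))
for v in verdicts:
    print(
        f"  {v.id:<13} pattern4={str(v.has_pattern4):<5} "
        f"pI={v.pI:5.2f}  candidate={v.is_srnase_candidate}"
    )

# synthetic annotation: the candidate gene with F-box genes 100-500 kb away
genes = [GeneFeature("srnase_like", "chr2", 50_000_000, 50_002_000)]
fbox = []
for i in range(10):
    name = f"fbox{i}"
    genes.append(GeneFeature(name, "chr2", 50_100_000 + i * 40_000, 50_101_000 + i * 40_000))
    fbox.append(name)

(locus,) = find_slocus(["srnase_like"], genes, fbox, flank_bp=1_000_000)
print(f"S-locus candidate: {locus.srnase_id} on {locus.chrom}")
print(f"linked F-box genes within 1 Mb: {len(locus.fbox_genes)}")
# An S-RNase with linked F-box genes is the genomic signature of a
# gametophytic self-incompatibility locus.
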