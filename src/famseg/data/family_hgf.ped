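# Four-generation hereditary gingival fibromatosis family, 25 individuals:
# 23 alive genotyped members (generations II-IV) plus the two deceased,
# ungenotyped generation-I founders (I-1 affected, I-2 unaffected).
#
# The published pedigree drawing is not machine-readable, so the exact
# sibling-vs-spouse topology within generations II-III below is ONE
# reconstruction consistent with the published member table and with the
# reported linkage result. It is constrained so that every genotyped carrier
# has a carrier parent in the pedigree and no genotyped non-carrier does,
# giving exactly 12 phase-known informative meioses (3 from the obligate
# carrier founder I-1, 9 from genotyped carrier parents), i.e. a maximum
# two-point LOD of 12*log10(2) = 3.612 under complete co-segregation.
# Consequences of that constraint, flagged as reconstruction choices:
#   - II-5 x II-6 are a married-in founder couple whose son III-9 (with his
#     married-in wife III-8) fathers the unaffected child IV-4;
#   - II-9 is a childless married-in relative;
#   - IV-1, IV-2 (proband) and IV-3 are siblings (children of III-2 x III-1);
#   - carriers III-4 and III-7 have no offspring in the pedigree.
#
# Columns: family_id individual_id father_id mother_id sex(1=M,2=F)
#          phenotype(2=affected,1=unaffected,0=unknown); 0 = missing parent.
HGF1 I-1   0     0     1 2
HGF1 I-2   0     0     2 1
HGF1 II-1  0     0     1 1
HGF1 II-2  I-1   I-2   2 2
HGF1 II-3  I-1   I-2   1 2
HGF1 II-4  0     0     2 1
HGF1 II-5  0     0     1 1
HGF1 II-6  0     0     2 1
HGF1 II-7  0     0     1 1
HGF1 II-8  I-1   I-2   2 2
HGF1 II-9  0     0     2 1
HGF1 III-1 0     0     2 1
HGF1 III-2 II-1  II-2  1 2
HGF1 III-3 II-1  II-2  2 2
HGF1 III-4 II-3  II-4  1 2
HGF1 III-5 0     0     2 1
HGF1 III-6 II-3  II-4  1 2
HGF1 III-7 II-7  II-8  2 2
HGF1 III-8 0     0     2 1
HGF1 III-9 II-5  II-6  1 1
HGF1 IV-1  III-2 III-1 1 2
HGF1 IV-2  III-2 III-1 2 2
HGF1 IV-3  III-2 III-1 2 2
HGF1 IV-4  III-9 III-8 2 1
HGF1 IV-5  III-6 III-5 1 2
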