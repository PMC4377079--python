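# Template for the LDL-cholesterol -> coronary artery disease worked example.
#
# Five LDL-C-associated variants (selected for no association with HDL-C or
# triglycerides, to limit pleiotropy), one per gene region.  The per-allele
# association estimates and standard errors are NOT reproduced here: fill in
# the numeric columns from the Supporting Information of the source
# publication (per-allele change in LDL-C with SE, and per-allele log odds
# ratio of CAD with SE from the GWAS meta-analysis of Waterworth et al.).
# Then run, for odds ratios per 30% reduction in LDL-C:
#
#   mrsummary estimate --input ldl_cad.csv --method all \
#       --rho-grid=-0.4,-0.2,-0.1,0,0.1,0.2,0.4 --or-delta=-0.3
#
# (--or-delta expresses the contrast in the units of beta_x; adjust if the
# LDL-C associations are not on a proportional/log scale.)
variant,beta_x,se_x,beta_y,se_y
PCSK9,,,,
SORT1,,,,
APOB,,,,
HMGCR,,,,
LDLR,,,,
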