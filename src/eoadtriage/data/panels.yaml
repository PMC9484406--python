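# Gene panels used for clinical classification.  Panels must be pairwise
# disjoint.  The GWAS susceptibility panel lists the 17 genes in which rare
# variants were reported plus 17 further AD GWAS loci genes; the latter are
# supplement-sourced placeholders and may be overridden by the user.
panels:
  ad_causative:
    - APP
    - PSEN1
    - PSEN2
  ad_risk:
    - TREM2
    - ABCA7
    - SORL1
  other_dementia:
    - CCNF
    - CHCHD10
    - CSF1R
    - DCTN1
    - FIG4
    - FUS
    - MAPT
    - NOTCH3
    - OPTN
    - SQSTM1
    - TYROBP
    - UBQLN2
  ad_gwas:
    - ADAM10
    - BIN1
    - CLU
    - CR1
    - ELAVL1
    - EP300
    - EPHA1
    - FERMT2
    - INPP5D
    - MARK2
    - MARK4
    - PICALM
    - PLCG2
    - PTK2B
    - RIN3
    - TOMM40
    - ZCWPW1
    # supplement-sourced remainder (user-overridable)
    - ABI3
    - ACE
    - APH1B
    - CASS4
    - CD2AP
    - CD33
    - ECHDC3
    - HLA-DRB1
    - IQCK
    - MS4A4A
    - MS4A6A
    - NCK2
    - SCIMP
    - SLC24A4
    - SPI1
    - TSPOAP1
    - WWOX
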