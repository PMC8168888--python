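# Stand-in feminine word list (openly authored; NOT the proprietary
# LIWC 2015 "she" category).
she
her
hers
herself
woman
women
female
girl
girls
daughter
daughters
mother
sister
wife
aunt
queen
madam
mrs
lady
ladies
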