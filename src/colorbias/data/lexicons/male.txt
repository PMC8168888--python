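# Stand-in masculine word list (openly authored; NOT the proprietary
# LIWC 2015 "he" category). A LIWC licensee can replace this file with the
# real category, one pattern per line, trailing * as stem wildcard.
he
his
him
himself
man
men
male
boy
boys
son
sons
father
brother
husband
uncle
king
sir
mr
gentleman
gentlemen
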