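# Stand-in negative-emotion word list (openly authored; NOT the proprietary
# LIWC 2015 "negemo" category).
hurt
ugly
nasty
sad*
angr*
hate*
bad
terrible
awful
fear*
cry*
pain*
worr*
lose
fail*
grief
lonely
cruel
enemy
disgust*
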