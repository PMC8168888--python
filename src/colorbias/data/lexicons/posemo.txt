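# Stand-in positive-emotion word list (openly authored; NOT the proprietary
# LIWC 2015 "posemo" category).
love
nice
sweet
happ*
joy*
good
great
wonderful
excellent
beautiful
friend*
laugh*
kind
hope*
win
success*
delight*
pleasant
warm
smile
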