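# Approximate single-type relative mutation rates (fold shifts) of European
# and East Asian vs African human populations, assembled from the human
# mutation-spectrum literature (Harris 2015 PNAS 112:3439-3444; Harris &
# Pritchard 2017 eLife 6:e24284).  Reported population differences in humans
# span roughly 0.9- to 2.0-fold; the TCC>T pulse in Europeans is the most
# prominent signature and is placed at the top of that range.  The remaining
# entries are the weaker reported signals (sub-1.5-fold).  Folds apply to the
# strand-collapsed (96-category) type, i.e. to both strand representatives.
population	mutation_type	fold	strength
EUR	TCC>T	2.0	strong
EUR	CCC>T	1.4	weak
EUR	ACC>T	1.3	weak
EUR	TCT>T	1.2	weak
EAS	TCC>T	1.3	weak
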