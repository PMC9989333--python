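# Four-population common chimpanzee model: Western (Pan troglodytes verus),
# Nigeria-Cameroon (P. t. ellioti), Central (P. t. troglodytes) and Eastern
# (P. t. schweinfurthii).
#
# APPROXIMATE TRANSCRIPTION.  Present-day effective sizes for Western (~5,700)
# and Central (~72,000) follow the estimates of Prado-Martinez et al. (2013)
# Nature 499:471-475 (Great Ape Diversity Panel demographic inference); the
# topology — (verus, ellioti) sister to (troglodytes, schweinfurthii) — and
# the remaining sizes/split times are literature-scale approximations (western
# clade ~0.55 Mya, verus/ellioti ~0.25 Mya, troglodytes/schweinfurthii
# ~0.15 Mya; 20-year generation time), not an exact copy of that study's
# supplementary model 4A, whose full parameter table is not reproduced here.
# Internal ancestors are folded into the epoch histories of a carrier
# population (Eastern into Central; Western into Nigeria-Cameroon; the
# western clade into Central at the root).
species: chimpanzee
generation_time_years: 20
time_units: generations
populations:
  - id: Central        # carries the Central/Eastern ancestor and the root
    epochs:
      - {start: 0, size: 72000}
      - {start: 7500, size: 50000}    # Central/Eastern ancestor
      - {start: 27500, size: 30000}   # common chimpanzee ancestor
  - id: Eastern
    epochs:
      - {start: 0, size: 25000}
  - id: NigeriaCameroon   # carries the Western/Nigeria-Cameroon ancestor
    epochs:
      - {start: 0, size: 10000}
      - {start: 12500, size: 15000}   # western-clade ancestor
  - id: Western
    epochs:
      - {start: 0, size: 5700}
splits:
  - {time: 7500,  child: Eastern, parent: Central}          # ~150 kya
  - {time: 12500, child: Western, parent: NigeriaCameroon}  # ~250 kya
  - {time: 27500, child: NigeriaCameroon, parent: Central}  # ~550 kya
migrations:
  # ongoing Central<->Eastern gene flow (Eastern chimpanzees show the highest
  # migration rates among the four populations)
  - {source: Central, dest: Eastern, rate: 5.0e-5, start: 0, end: 7500}
  - {source: Eastern, dest: Central, rate: 5.0e-5, start: 0, end: 7500}
  # weak Nigeria-Cameroon <-> Central contact
  - {source: NigeriaCameroon, dest: Central, rate: 5.0e-6, start: 0, end: 12500}
  - {source: Central, dest: NigeriaCameroon, rate: 5.0e-6, start: 0, end: 12500}
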