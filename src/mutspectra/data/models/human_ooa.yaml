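# Three-population human out-of-Africa model (African / European / East Asian
# plus the out-of-Africa bottleneck ghost population "OOA").
#
# Parameter values transcribed from Gravel et al. (2011) PNAS 108:11983-11988,
# Table 2, "Low-coverage + exons" maximum-likelihood fit:
#   N_A = 7,310; N_AF = 14,474; T_AF = 148 kya; N_B = 1,861; T_B = 51 kya;
#   T_EU-AS = 23 kya; N_EU0 = 1,032 (r_EU = 0.38%/gen); N_AS0 = 554
#   (r_AS = 0.48%/gen); m_AF-B = 15e-5; m_AF-EU = 2.5e-5; m_AF-AS = 0.78e-5;
#   m_EU-AS = 3.11e-5.  Generation time 25 years, so
#   T_AF = 5,920, T_B = 2,040, T_EU-AS = 920 generations.
# Present-day EUR/EAS sizes below are N0 * exp(r * T_EU-AS).
species: human
generation_time_years: 25
time_units: generations
populations:
  - id: AFR
    epochs:
      - {start: 0, size: 14474}
      - {start: 5920, size: 7310}
  - id: OOA            # out-of-Africa bottleneck population, extant 920-2040 gens ago
    epochs:
      - {start: 0, size: 1861}
  - id: EUR
    epochs:
      - {start: 0, size: 33807, growth_rate: 0.0038}   # 1032 * e^(0.0038*920)
  - id: EAS
    epochs:
      - {start: 0, size: 45851, growth_rate: 0.0048}   # 554 * e^(0.0048*920)
splits:
  - {time: 920,  child: EUR, parent: OOA}
  - {time: 920,  child: EAS, parent: OOA}
  - {time: 2040, child: OOA, parent: AFR}
migrations:
  # symmetric continuous migration, per-lineage per-generation
  - {source: AFR, dest: OOA, rate: 15.0e-5, start: 920, end: 2040}
  - {source: OOA, dest: AFR, rate: 15.0e-5, start: 920, end: 2040}
  - {source: AFR, dest: EUR, rate: 2.5e-5,  start: 0, end: 920}
  - {source: EUR, dest: AFR, rate: 2.5e-5,  start: 0, end: 920}
  - {source: AFR, dest: EAS, rate: 0.78e-5, start: 0, end: 920}
  - {source: EAS, dest: AFR, rate: 0.78e-5, start: 0, end: 920}
  - {source: EUR, dest: EAS, rate: 3.11e-5, start: 0, end: 920}
  - {source: EAS, dest: EUR, rate: 3.11e-5, start: 0, end: 920}
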