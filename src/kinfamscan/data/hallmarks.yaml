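# Operational kinase hallmark patterns, in PROSITE grammar.
#
# These stand in for the three PROSITE entries a kinase survey checks
# (an ATP-binding region, a serine/threonine active site, and the kinase
# catalytic domain). They are modeled on the universal kinase subdomain
# anatomy -- the glycine-rich loop + VAIK lysine, the HRD catalytic loop,
# and the HRD..DFG catalytic core -- rather than transcribed from the
# PROSITE database (the real kinase-domain entry is a profile, not a
# pattern). Swap in your own definitions, or a true profile scanner, by
# pointing the pipeline at a different patterns file.
hallmarks:
  - name: atp_binding
    pattern: "G-x-G-x(2)-[SG]-x-V-x(8,20)-[AV]-x-K"
  - name: active_site
    pattern: "H-R-D-[LIVMF]-K-x(2)-N"
  - name: kinase_domain
    pattern: "H-R-D-[LIVMF]-K-x(2)-N-x(4,12)-D-F-G"
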