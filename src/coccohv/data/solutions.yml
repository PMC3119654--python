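# Electrophysiology solution compositions (mM of free ion, totals over all salts).
# E* are bath (external) solutions, P* pipette (internal) solutions, following the
# published recording conditions for C. pelagicus protoplasts and HEK293 cells.
# H+ is never listed: it is derived from pH. Recording temperature 20 degC.
#
# Assumptions (flagged, not printed in the source legends):
#   * Fig-2-style pipette variants (P_KCl80 / P_KCl400 / P_KGlu200) carry pH 7.5.
#   * NMDG solutions (P4/E4/E5) assume NMDG titrated with HCl, so NMDG counts
#     toward Cl-.
#   * Glutamate, sorbitol, glucose, EGTA and pH buffers are impermeant and omitted
#     from the ion lists.
solutions:
  E1:   # artificial seawater bath: NaCl 450, KCl 8, MgCl2 30, MgSO4 16, CaCl2 10, NaHCO3 2, HEPES 20
    ions: {Na: 452, K: 8, Cl: 538, Mg: 46, Ca: 10}
    pH: 8.0
    buffer: "HEPES 20"
  E3:   # HEK bath: NaCl 160, KCl 2, MgCl2 1, CaCl2 1, glucose 20, HEPES 100
    ions: {Na: 160, K: 2, Cl: 166, Mg: 1, Ca: 1}
    pH: 7.8
    buffer: "HEPES 100"
  E4:   # HEK bath: NMDG 75, MgCl2 3, CaCl2 1, glucose 160, HEPES 100
    ions: {Cl: 83, Mg: 3, Ca: 1}
    pH: 7.8
    buffer: "HEPES 100"
  E5:   # E4 with MES in place of HEPES, pH 6.5
    ions: {Cl: 83, Mg: 3, Ca: 1}
    pH: 6.5
    buffer: "MES 100"
  P1a:  # pipette: K-glutamate 200, MgCl2 5, EGTA 5, HEPES 100
    ions: {K: 200, Cl: 10, Mg: 5}
    pH: 7.5
    buffer: "HEPES 100"
  P1b:  # pipette: K-glutamate 200, MgCl2 5, EGTA 5, PIPES 1 (BCECF free acid added)
    ions: {K: 200, Cl: 10, Mg: 5}
    pH: 7.5
    buffer: "PIPES 1"
  P2:   # pipette: TEA-Cl 200, MgCl2 5, EGTA 5, HEPES 5
    ions: {Cl: 210, Mg: 5}
    pH: 7.5
    buffer: "HEPES 5"
  P3:   # HEK pipette: NaCl 30, KCl 100, MgCl2 3, EGTA 1, HEPES 100
    ions: {Na: 30, K: 100, Cl: 136, Mg: 3}
    pH: 7.0
    buffer: "HEPES 100"
  P4:   # HEK pipette: NMDG 65, MgCl2 3, EGTA 1, HEPES 150, glucose 70
    ions: {Cl: 71, Mg: 3}
    pH: 7.0
    buffer: "HEPES 150"
  P_KCl80:   # K/Cl-varied pipette: KCl 80, MgCl2 5, EGTA 5, HEPES 5
    ions: {K: 80, Cl: 90, Mg: 5}
    pH: 7.5
    buffer: "HEPES 5"
  P_KCl400:  # KCl 400, MgCl2 5, EGTA 5, HEPES 5
    ions: {K: 400, Cl: 410, Mg: 5}
    pH: 7.5
    buffer: "HEPES 5"
  P_KGlu200: # K-glutamate 200, MgCl2 5, EGTA 5, HEPES 5
    ions: {K: 200, Cl: 10, Mg: 5}
    pH: 7.5
    buffer: "HEPES 5"
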