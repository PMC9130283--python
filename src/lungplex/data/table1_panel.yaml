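# Default marker panel: the 24-antibody MILAN staining design for mouse lung,
# 11 rounds, <=3 unconjugated primaries per round plus DAPI in every round.
# Channel = fluorophore class of the secondary (FITC ~ AF488, TRITC ~ rhodamine,
# FARRED ~ AF647).  `targets` is the cell-type signature of the marker (empty =
# measured-only, no lineage information).  `classify` flags membership in the
# 23-marker classification set (BCRP is carried as measured-only).
name: mouse_lung_24plex
markers:
  - {short_name: COLL1,  round: 1,  channel: FARRED, host: "mo IgG3",     targets: [stromal], classify: true}
  - {short_name: aSMA,   round: 1,  channel: TRITC,  host: "mo IgG2a",    targets: [myofibroblast_smc], classify: true}
  - {short_name: SM22,   round: 2,  channel: FITC,   host: "goat",        targets: [myofibroblast_smc], classify: true}
  - {short_name: DESM,   round: 2,  channel: FARRED, host: "mo IgG1",     targets: [myofibroblast_smc], classify: true}
  - {short_name: vWF,    round: 3,  channel: FITC,   host: "goat",        targets: [vasculature], classify: true}
  - {short_name: PanCK,  round: 3,  channel: FARRED, host: "mo IgG1",     targets: [AT1, AT2, transitional_AT, bronchial_goblet], classify: true}
  - {short_name: MUC5b,  round: 4,  channel: FARRED, host: "mo IgG1",     targets: [bronchial_goblet], classify: true}
  - {short_name: CD206,  round: 4,  channel: FITC,   host: "goat",        targets: [macrophage], classify: true}
  - {short_name: SPD,    round: 5,  channel: FARRED, host: "mo IgG1",     targets: [AT2, transitional_AT], classify: true}
  - {short_name: PAX5,   round: 5,  channel: TRITC,  host: "rb Mab",      targets: [B_cell], classify: true}
  - {short_name: AQP5,   round: 6,  channel: FARRED, host: "mo IgG1",     targets: [AT1, transitional_AT], classify: true}
  - {short_name: OPN,    round: 6,  channel: FITC,   host: "goat",        targets: [macrophage, neutrophil], classify: true}
  - {short_name: PDPN,   round: 7,  channel: FITC,   host: "s.hamster",   targets: [AT1, transitional_AT], classify: true}
  - {short_name: MMP7,   round: 7,  channel: TRITC,  host: "rb Mab",      targets: [], classify: true}
  - {short_name: NKX2-1, round: 8,  channel: FARRED, host: "mo IgG1",     targets: [AT2, transitional_AT], classify: true}
  - {short_name: CD3,    round: 8,  channel: TRITC,  host: "rb poly",     targets: [T_cell], classify: true}
  - {short_name: RAGE,   round: 9,  channel: FARRED, host: "mo IgG1",     targets: [AT1, transitional_AT], classify: true}
  - {short_name: MPO,    round: 9,  channel: TRITC,  host: "rb poly",     targets: [neutrophil], classify: true}
  - {short_name: HOP,    round: 10, channel: FARRED, host: "mo IgG1",     targets: [AT1, transitional_AT], classify: true}
  - {short_name: ABCA3,  round: 10, channel: TRITC,  host: "mo IgG2a",    targets: [AT2, transitional_AT], classify: true}
  - {short_name: FGF10,  round: 10, channel: FITC,   host: "goat",        targets: [stromal], classify: true}
  - {short_name: VIM,    round: 11, channel: FITC,   host: "mo IgG1",     targets: [stromal], classify: true}
  - {short_name: P-gP,   round: 11, channel: TRITC,  host: "rb poly",     targets: [], classify: true}
  - {short_name: BCRP,   round: 11, channel: FARRED, host: "rat IgG2a",   targets: [], classify: false}
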