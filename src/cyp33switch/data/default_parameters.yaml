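# Default binding constants for the Cyp33 / MLL1 PHD3-BRD / H3K4me3 / RNA switch.
# Units: dissociation constants in uM; kon_default in uM^-1 s^-1.
# Species labels: M = MLL1 PHD3-BRD reader module, H = H3K4me3 tail,
# C = Cyp33 (RRM), R = single-site RNA (UAAUGU motif). Complexes concatenate
# their monomer labels. PHD3 denotes the isolated PHD3 finger (assay-only).
species: [M, H, C, R]
kon_default: 10.0
constants:
  - pair: [M, H]
    kd_uM: 4.0
    censored: false
    source: MLL1 PHD3-BRD reader binding H3K4me3 (prior ITC work)
  - pair: [C, M]
    kd_uM: 4.6
    censored: false
    source: Cyp33 RRM binding MLL1 PHD3, ITC
  - pair: [CM, H]
    kd_uM: 70.0
    censored: false
    source: H3K4me3 binding the Cyp33 RRM / MLL1 PHD3 complex, ITC
  - pair: [C, R]
    kd_uM: 300.0
    censored: false
    source: Cyp33 wild type binding UAAUGU RNA, NMR titration
  - pair: [R, H]
    kd_uM: 30.0
    censored: false
    source: H3K4me3 peptide binding UAAUGU RNA, ITC
  - pair: [PHD3, H]
    kd_uM: 51.0
    censored: false
    source: isolated MLL1 PHD3 binding H3K4me3, ITC
  - pair: [CdaM, H]
    kd_uM: 24.0
    censored: false
    source: H3K4me3 binding the Cyp33 RRM-delta-alpha3 / MLL1 PHD3 complex, ITC
  - pair: [Cwlf, R]
    kd_uM: 70.0
    censored: false
    source: Cyp33 WLF alpha3 mutant binding UAAUGU RNA, NMR titration
  - pair: [Ck83a, R]
    kd_uM: 1800.0
    censored: false
    source: Cyp33 K83A mutant binding UAAUGU RNA, NMR titration
  - pair: [Crk, R]
    kd_uM: 2000.0
    censored: false
    source: Cyp33 RK double mutant binding UAAUGU RNA, NMR titration
  - pair: [Ckrk, R]
    kd_uM: 10000.0
    censored: true
    source: Cyp33 KRK triple mutant, RNA binding below detection (lower bound)
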