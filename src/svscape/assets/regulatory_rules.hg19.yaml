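# Non-coding regulatory SV rules (hg19): locus predicates describing SVs
# that cis-activate an oncogene via enhancer hijacking, regulatory-region
# duplication, or regulatory deletion.  All coordinates are 1-based
# inclusive.  Each rule is an AND of its clauses; `any_of` expresses
# alternative clause sets.  Edit freely: the engine validates intervals at
# load time.
#
# Clause vocabulary:
#   sv_types: allowed SV types            intra_only: same-chromosome only
#   max_span / min_span: bp (max is strict upper bound)
#   breakpoint_in: >=1 breakpoint inside one of the regions
#   partner_in: the other breakpoint must be inside one of these regions
#   overlaps: the SV interval intersects the region
#   not_contains: reject when the SV interval fully contains the region
#                 (optionally restricted to sv_types)
#   exclude_breakpoint_in: reject when any breakpoint is inside
#   exclude_overlap: reject when the SV interval intersects (by sv_types)

rules:
  - name: NME           # NOTCH-MYC enhancer duplication (B-ALL, T-ALL, NBL)
    sv_types: [DUP]
    overlaps: {chrom: chr8, start: 130161775, end: 130202012}

  - name: BENC          # blood enhancer cluster duplication near MYC
    sv_types: [DUP]
    overlaps: {chrom: chr8, start: 130558973, end: 130724424}

  - name: PVT1          # MYC/PVT1 regulatory region translocation
    sv_types: [TRA]
    breakpoint_in:
      - {chrom: chr8, start: 128753680, end: 129113499}

  - name: TAL1          # deletions fusing the TAL1 promoter region to STIL
    sv_types: [DEL]
    breakpoint_in:
      - {chrom: chr1, start: 47681962, end: 47698007}   # TAL1 (reverse)
      - {chrom: chr1, start: 47698008, end: 47779819}   # upstream incl. STIL

  - name: DUX4-IGH      # DUX4 activation by translocation into IGH (B-ALL)
    sv_types: [TRA]
    breakpoint_in:
      - {chrom: chr4, start: 190980000, end: 191041000}  # D4Z4 repeat / DUX4
    partner_in:
      - {chrom: chr14, start: 106032614, end: 107288051} # IGH

  - name: TERT          # TERT enhancer hijacking in neuroblastoma
    breakpoint_in:
      # upstream window; printed bounds were reversed, normalized here (REVIEW)
      - {chrom: chr5, start: 1325184, end: 1925183}
      # 6-40 kb downstream of the reverse-transcribed gene
      - {chrom: chr5, start: 1213282, end: 1247282}
    not_contains:
      sv_types: [DEL, DUP]
      region: {chrom: chr5, start: 1253282, end: 1295183}   # TERT gene body

  - name: GFI1          # GFI1 enhancer hijacking in medulloblastoma
    sv_types: [TRA]
    breakpoint_in:
      - {chrom: chr1, start: 92838318, end: 93054433}   # GFI1 +/- 102 kb

  - name: GFI1B         # GFI1B activation by intra-chromosomal rearrangement
    intra_only: true
    # upper bound of the printed interval exceeds the chromosome; plausible
    # digit slip normalized to 135,856,204 (REVIEW)
    overlaps: {chrom: chr9, start: 134279237, end: 135856204}
    breakpoint_in:
      - {chrom: chr9, start: 134279237, end: 135867084}  # upstream or within GFI1B
    max_span: 4000000     # DEL/DUP < 4 Mb
    not_contains:
      region: {chrom: chr9, start: 135854097, end: 135867084}  # whole GFI1B

  - name: BCL11B        # BCL11B enhancer hijacking / downstream duplication
    any_of:
      - sv_types: [DUP]
        overlaps: {chrom: chr14, start: 98905624, end: 99635623}  # 730 kb downstream
      - breakpoint_in:
          - {chrom: chr14, start: 99535624, end: 99837861}  # +/- 100 kb of BCL11B
        partner_in:
          - {chrom: chr6, start: 156000000, end: 157099062}  # gene desert upstream of ARID1B
          - {chrom: chr8, start: 130558973, end: 130724424}  # BENC within CCDC26
          - {chrom: chr7, start: 92234235, end: 92465908}    # CDK6
          - {chrom: chr12, start: 11802788, end: 12048325}   # ETV6
          - {chrom: chr3, start: 18386875, end: 18486550}    # SATB1

  - name: SNCAIP        # SNCAIP duplication activating PRDM6 (medulloblastoma)
    intra_only: true
    max_span: 1000001     # "no larger than 1 Mb"
    overlaps: {chrom: chr5, start: 121647854, end: 121799466}

  - name: FLT3          # deletions upstream of FLT3 (B-ALL)
    sv_types: [DEL]
    max_span: 1000000     # total span < 1 Mb (strict)
    breakpoint_in:
      - {chrom: chr13, start: 28500000, end: 28900000}

  - name: MECOM         # MECOM-adjacent rearrangements in AML
    breakpoint_in:
      - {chrom: chr3, start: 168701287, end: 168801286}  # 100 kb flank (left)
      - {chrom: chr3, start: 169381407, end: 169481406}  # 100 kb flank (right)
    exclude_breakpoint_in:
      - {chrom: chr3, start: 168801287, end: 169381406}  # within the gene
    not_contains:
      sv_types: [DEL, DUP]
      region: {chrom: chr3, start: 168801287, end: 169381406}

  - name: CEBPD         # CEBPD-adjacent translocations in ALL
    sv_types: [TRA]
    breakpoint_in:
      - {chrom: chr8, start: 48549475, end: 48750726}    # CEBPD +/- 100 kb

  - name: CRLF2         # CRLF2-adjacent events in ALL (PAR1)
    breakpoint_in:
      - {chrom: chrX, start: 1214890, end: 1431616}      # CRLF2 +/- 100 kb
    exclude_overlap:
      sv_types: [DEL]
      region: {chrom: chrX, start: 1314890, end: 1331616}  # the gene itself
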