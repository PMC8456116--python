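# The 21-gene marker pool used by the simulation studies: per-gene counts
# of SNVs (q1) and CNV segments (q2).  The first gene, GNB1, hosts the
# causal variants in every non-null setting.
genes:
  - {gene_id: GNB1,         chromosome: "1",  q1: 15, q2: 10}
  - {gene_id: LOC102467217, chromosome: "5",  q1: 7,  q2: 1}
  - {gene_id: PDE5A,        chromosome: "4",  q1: 11, q2: 1}
  - {gene_id: C11orf48,     chromosome: "11", q1: 2,  q2: 2}
  - {gene_id: CTTNBP2NL,    chromosome: "1",  q1: 5,  q2: 2}
  - {gene_id: PTCH1,        chromosome: "9",  q1: 12, q2: 3}
  - {gene_id: SLC25A25,     chromosome: "9",  q1: 4,  q2: 3}
  - {gene_id: CCL15-CCL14,  chromosome: "17", q1: 9,  q2: 4}
  - {gene_id: CD164,        chromosome: "6",  q1: 7,  q2: 4}
  - {gene_id: IGSF22,       chromosome: "11", q1: 10, q2: 5}
  - {gene_id: CRBN,         chromosome: "3",  q1: 9,  q2: 5}
  - {gene_id: VAMP1,        chromosome: "12", q1: 5,  q2: 6}
  - {gene_id: CLEC17A,      chromosome: "19", q1: 7,  q2: 6}
  - {gene_id: DMGDH,        chromosome: "5",  q1: 21, q2: 7}
  - {gene_id: LPA,          chromosome: "6",  q1: 24, q2: 7}
  - {gene_id: CD276,        chromosome: "15", q1: 7,  q2: 8}
  - {gene_id: MED13L,       chromosome: "12", q1: 19, q2: 8}
  - {gene_id: KBTBD12,      chromosome: "3",  q1: 22, q2: 9}
  - {gene_id: HLA-DQB2,     chromosome: "6",  q1: 19, q2: 9}
  - {gene_id: GM2A,         chromosome: "5",  q1: 12, q2: 10}
  - {gene_id: LRRC63,       chromosome: "13", q1: 20, q2: 10}
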