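compound,mechanism,respiratory_risk,ic50_um
AZ1,Tyrosine Kinase inhibitor,yes,11.0
AZ2,Tyrosine Kinase inhibitor,yes,NA
AZ3,Protein Kinase inhibitor,yes,9.6
AZ4,Antimicrobial,yes,16.8
AZ5,Tyrosine Kinase inhibitor,yes,27.9
AZ6,Adrenergic receptor agonist,yes,35.3
AZ7,Tyrosine Kinase inhibitor,yes,46.7
AZ8,Phosphodiesterase antagonist,yes,36.4
Cadmium chloride,NA,yes,3.7
AZ10,Phosphoinositol antagonist,yes,2.1
AZ11,Mast cell stabilizer,no,NA
AZ12,Muscarinic acetylcholine receptor antagonist,no,NA
AZ13,Acetylcholine receptor antagonist,no,NA
AZ14,Adrenergic receptor agonist,no,NA
AZ15,Muscarinic acetylcholine receptor antagonist,no,NA
AZ16,Adrenergic receptor agonist,no,NA
AZ17,Serine Proteinase antagonist,no,NA
AZ18,Muscarinic acetylcholine receptor antagonist,no,NA
AZ19,Antibiotic,no,NA
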