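descriptor_id,description,citation,A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
isoelectric_point,Isoelectric point,"Zimmerman et al. (1968), J Theor Biol 21:170 (best-match accession)",6.00,10.76,5.41,2.77,5.05,5.65,3.22,5.97,7.59,6.02,5.98,9.74,5.74,5.48,6.30,5.68,5.66,5.89,5.66,5.96
vdw_volume_norm,Normalized van der Waals volume,"Fauchere et al. (1988), Int J Pept Protein Res 32:269 (best-match accession)",1.00,6.13,2.95,2.78,2.43,3.95,3.78,0.00,4.66,4.00,4.00,4.77,4.43,5.89,2.72,1.60,2.60,8.08,6.47,3.00
alpha_helix_beta_proteins,Alpha-helix indices for beta-proteins,synthetic stand-in scale (helix propensity profile; decorrelated from co-packaged scales),0.55,0.55,1.60,0.55,0.75,0.73,0.71,0.55,0.99,0.94,1.19,0.77,0.55,0.67,0.42,0.56,0.55,0.55,0.55,0.61
beta_strand_beta_proteins,Beta-strand indices for beta-proteins,synthetic stand-in scale (strand propensity profile; decorrelated from co-packaged scales),0.55,1.29,0.97,1.40,0.55,1.55,0.60,1.55,0.80,1.60,0.62,0.55,0.55,0.55,0.50,0.66,0.66,1.39,0.57,1.70
sidechain_stability,Side-chain contribution to protein stability,synthetic stand-in scale (high in Phe/Trp; decorrelated from co-packaged scales),2.80,1.92,2.30,2.73,2.73,2.46,1.12,0.00,1.85,0.64,1.96,2.36,0.21,3.60,2.60,2.80,2.80,3.70,-1.20,2.80
atom_atom_potential,The stability scale from knowledge-based atom-atom potential,synthetic stand-in scale (high in Phe/Trp/Tyr; decorrelated from co-packaged scales),1.25,-1.04,0.86,-0.73,-0.42,-1.23,1.25,1.25,1.13,0.69,-1.40,1.25,-1.40,1.60,-0.09,1.25,-1.15,1.70,1.45,1.25
hydropathy,Hydropathy index,"Kyte & Doolittle (1982), J Mol Biol 157:105",1.80,-4.50,-3.50,-3.50,2.50,-3.50,-3.50,-0.40,-3.20,4.50,3.80,-3.90,1.90,2.80,-1.60,-0.80,-0.70,-0.90,-1.30,4.20
turn_frequency_norm,Normalized frequency of turn,Chou & Fasman (1978) turn propensities (best-match accession),0.66,0.95,1.56,1.46,1.19,0.98,0.74,1.56,0.95,0.47,0.59,1.01,0.60,0.60,1.52,1.43,0.96,0.96,1.14,0.50
free_energy_beta,Free energy in beta-strand region,synthetic stand-in scale (high cost for Pro/Gly in strand; decorrelated from co-packaged scales),1.20,1.20,0.65,0.58,-0.60,0.21,1.00,1.30,1.20,1.20,1.20,-0.60,1.20,1.20,2.20,0.80,-0.55,1.20,-0.54,-0.60
free_energy_alpha,Free energy in alpha-helical region,synthetic stand-in scale (high cost for Pro/Gly in helix; decorrelated from co-packaged scales),-0.60,0.06,0.07,0.20,1.08,1.25,1.25,1.40,1.25,1.25,1.25,1.25,-0.60,1.25,3.16,-0.60,1.25,0.29,0.84,1.25
polarity,Polarity,"Zimmerman et al. (1968), J Theor Biol 21:170 (best-match accession)",0.00,52.00,3.38,49.70,1.48,3.53,49.90,0.00,51.60,0.13,0.13,49.50,1.43,0.35,1.58,1.67,1.66,2.10,1.61,0.13
sidechain_interaction,Side chain interaction parameter,synthetic stand-in scale (high in Lys/Pro/Gln/Glu/Asp; decorrelated from co-packaged scales),0.72,0.78,0.78,0.90,0.78,0.92,0.95,0.16,-0.55,0.78,0.52,1.05,0.62,0.78,0.98,0.59,-0.60,0.12,0.67,0.78
aa_distribution,Amino acid distribution,synthetic stand-in scale (bulk composition profile; decorrelated from co-packaged scales),5.30,5.62,4.38,5.87,2.26,3.88,5.38,5.44,2.75,4.54,8.57,5.44,2.40,4.66,4.48,6.03,6.17,5.23,6.16,4.83
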