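taxon_id,functional_group,wall_type,display_name,assignment_basis
Ah,symbiont_bearing,porcellaneous,Amphisorus hemprichii,stated
Bsp,symbiont_bearing,porcellaneous,Borelis sp.,stated
Cf,heterotrophic,hyaline,Cibicides fletcheri,stated
Cl,heterotrophic,hyaline,Cibicides lobatulus,stated
Csp,heterotrophic,hyaline,Cibicides sp. (juvenile),inferred
Cs,heterotrophic,hyaline,Cibicidoides schmitti,stated
Ecs,opportunistic,hyaline,Elphidium crispum subcrispum,stated
Em,opportunistic,hyaline,Elphidium macellum,stated
Ep,opportunistic,hyaline,Elphidium postulosum,stated
Gv,heterotrophic,hyaline,Gypsina vesicularis,stated
Mb,heterotrophic,hyaline,Miniacina barringtonensis,stated
Msp,heterotrophic,hyaline,Miniacina sp.,stated
NHsp,heterotrophic,porcellaneous,Neohauerina or Hauerina sp.,inferred
Nsp,heterotrophic,agglutinated,Nouria sp.,inferred
Pd,heterotrophic,porcellaneous,Parahauerina displicata,stated
Pc,heterotrophic,hyaline,Poroeponides cribrorepandus,stated
Qb,heterotrophic,porcellaneous,Quinqueloculina blackbeachensis,stated
Qg,heterotrophic,porcellaneous,Quinqueloculina galapagosensis,stated
Qs,heterotrophic,porcellaneous,Quinqueloculina suborbicularis,inferred
Rmc,heterotrophic,hyaline,Rotorbinella mira clarionensis,stated
Rmg,heterotrophic,hyaline,Rotorbinella mira galapagosensis,stated
Sm,symbiont_bearing,porcellaneous,Sorites marginalis,stated
Sg,heterotrophic,hyaline,Sphaerogypsina globulus,stated
Ta,heterotrophic,porcellaneous,Triloculina ashbrooki,inferred
Usp1,heterotrophic,agglutinated,Unidentifiable agglutinated specimens 1,inferred
Usp2,heterotrophic,agglutinated,Unidentifiable agglutinated specimens 2,inferred
Usp3,heterotrophic,agglutinated,Unidentifiable agglutinated specimens 3,inferred
Usp4,heterotrophic,agglutinated,Unidentifiable agglutinated specimens 4,inferred
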