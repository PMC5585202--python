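taxon,clade,N,K,D,C,L,H,M
Mus musculus,outgroup,102,220,0.043,0.338,3.274,0.964,7
Tupaia sp.,outgroup,98,206,0.043,0.336,3.320,0.991,9
Cynocephalus volans,outgroup,97,239,0.051,0.349,3.195,0.834,8
Lemur catta,strepsirrhine,103,224,0.043,0.420,3.338,0.928,7
Propithecus verreauxi,strepsirrhine,102,225,0.044,0.436,3.321,0.897,7
Loris tardigradus,strepsirrhine,105,224,0.041,0.399,3.387,0.921,11
Nycticebus pygmaeus,strepsirrhine,109,233,0.040,0.416,3.409,0.940,8
Tarsius syrichta,tarsier,109,236,0.040,0.433,3.389,0.931,7
Callithrix jacchus,nwm,99,216,0.045,0.369,3.326,0.926,5
Saimiri sciureus,nwm,98,216,0.045,0.389,3.295,0.910,6
Aotus nancymaae,nwm,99,213,0.044,0.377,3.355,0.922,5
Pithecia pithecia,nwm,98,215,0.045,0.381,3.329,0.894,4
Colobus guereza,owm,103,220,0.042,0.406,3.368,0.930,8
Cercopithecus diana,owm,105,223,0.041,0.418,3.387,0.953,11
Papio anubis,owm,105,228,0.042,0.424,3.351,0.950,11
Macaca fascicularis,owm,105,228,0.042,0.426,3.390,0.930,10
Hylobates lar,hominoid,101,238,0.047,0.382,3.320,0.827,8
Pongo pygmaeus,hominoid,94,223,0.051,0.376,3.300,0.790,6
Gorilla gorilla,hominoid,92,223,0.053,0.404,3.277,0.765,8
Pan troglodytes,hominoid,99,245,0.051,0.405,3.313,0.788,11
Pan paniscus,hominoid,95,217,0.049,0.423,3.296,0.845,7
Homo sapiens,hominoid,94,193,0.044,0.380,3.410,0.923,5
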