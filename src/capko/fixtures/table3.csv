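recipe,food,ingredient,fresh_weight_g,salted,is_source,study
napa_1,napa cabbage kimchi,main vegetables,100,0,0,Cho et al. 2004
napa_1,napa cabbage kimchi,radish,13.0,0,0,Cho et al. 2004
napa_1,napa cabbage kimchi,green onion,2.0,0,0,Cho et al. 2004
napa_1,napa cabbage kimchi,red pepper powder,3.5,0,1,Cho et al. 2004
napa_1,napa cabbage kimchi,garlic,1.4,0,0,Cho et al. 2004
napa_1,napa cabbage kimchi,ginger,0.6,0,0,Cho et al. 2004
napa_1,napa cabbage kimchi,salted seafood/fish sauce,2.2,0,0,Cho et al. 2004
napa_2,napa cabbage kimchi,main vegetables,100,1,0,Choi et al. 2014
napa_2,napa cabbage kimchi,radish,11.4,0,0,Choi et al. 2014
napa_2,napa cabbage kimchi,green onion,2.1,0,0,Choi et al. 2014
napa_2,napa cabbage kimchi,red pepper powder,1.5,0,1,Choi et al. 2014
napa_2,napa cabbage kimchi,garlic,0.9,0,0,Choi et al. 2014
napa_2,napa cabbage kimchi,ginger,0.4,0,0,Choi et al. 2014
napa_2,napa cabbage kimchi,salted seafood/fish sauce,3.0,0,0,Choi et al. 2014
cubed_radish,cubed Korean radish kimchi,main vegetables,100,1,0,Choi et al. 2014
cubed_radish,cubed Korean radish kimchi,green onion,10.4,0,0,Choi et al. 2014
cubed_radish,cubed Korean radish kimchi,red pepper powder,2.4,0,1,Choi et al. 2014
cubed_radish,cubed Korean radish kimchi,garlic,2.1,0,0,Choi et al. 2014
cubed_radish,cubed Korean radish kimchi,ginger,0.9,0,0,Choi et al. 2014
cubed_radish,cubed Korean radish kimchi,salted seafood/fish sauce,4.3,0,0,Choi et al. 2014
watery,watery kimchi,main vegetables,45,0,0,Kong et al. 2016
watery,watery kimchi,radish,26.9,0,0,Kong et al. 2016
watery,watery kimchi,green onion,1.9,0,0,Kong et al. 2016
watery,watery kimchi,red pepper powder,0.7,0,1,Kong et al. 2016
watery,watery kimchi,garlic,1.2,0,0,Kong et al. 2016
watery,watery kimchi,ginger,0.9,0,0,Kong et al. 2016
watery,watery kimchi,salted seafood/fish sauce,1.0,0,0,Kong et al. 2016
watery,watery kimchi,water,100,0,0,Kong et al. 2016
young_radish,young radish kimchi,main vegetables,100,0,0,Kong et al. 2016
young_radish,young radish kimchi,green onion,8.0,0,0,Kong et al. 2016
young_radish,young radish kimchi,red pepper powder,4.2,0,1,Kong et al. 2016
young_radish,young radish kimchi,garlic,2.9,0,0,Kong et al. 2016
young_radish,young radish kimchi,ginger,1.6,0,0,Kong et al. 2016
young_radish,young radish kimchi,salted seafood/fish sauce,3.7,0,0,Kong et al. 2016
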