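(lobe_finned_fish,(Mammalia,((tuatara,(lizards,snakes))nodeC,(Testudines,(Crocodylia,Aves))nodeB)nodeDiapsida)nodeAmniota)nodeA;
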