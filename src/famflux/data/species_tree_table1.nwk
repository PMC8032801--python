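((Lec,Pm)Petromyzontiformes,((Cm,(Le,Rt))Chondrichthyes,(Lo,(((Aa,Ar),Aj)Elopomorpha,(Sf,((Ch,((Dr,((Lw,Pp),(Cc,(Sa,(Sg,Sr)))))Cypriniformes,((Am,Pyn),Ip)Characiphysae)Otophysa)Otomorpha,((El,Ss)Protacanthopterygii,(Gm,((Bp,(Sh,(Pem,Ps)))Gobiaria,((Hc,(To,Pa)Pelagiaria)Scombrimorpharia,((Moa,(Lac,(Po,(Py,Cs)))Carangaria),(((Stp,(Ac,(On,(Hb,(Mz,(Mc,(Nb,Pun))))))Cichliformes),(Ol,((Nf,Al),(Km,(Fh,((Cn,Cv),((Pr,(Pl,(Pf,Pom))),(Xc,(Xh,Xm)))))))Cyprinodontiformes)Atherinomorphae)Ovalentaria,(Lb,((Mom,(Tn,(Tf,Tr)))Tetraodontiformes,((Lc,Mim)Sciaenidae,((Dl,Ms)Moronidae,(Ga,(Af,(Cr,(Nc,(Sn,(Ses,(Ser,(Sem,Sea))))Sebastes))))))))Eupercaria))))Percomorphaceae)Neoteleostei)Euteleosteomorpha)Clupeocephala))Teleostei)Osteichthyes)Gnathostomata)Vertebrata;
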