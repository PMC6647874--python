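>rscC|structural-conserved synthetic stand-in sequence
MYGESTYVGNFQDRANDFRMEILRIIEKVKLTILDRTAPKAHFKDVNMVSGPSAVKTTLLGPLGRDLTEF
QQDIRLVCKRKCPESKYIKADINQKSALFAIHPYYNDHSIHDAGFCIRPDRDRLLFAVVGPVCGGVLFNY
DVLRVGFEVMNAKSAPSGDDSLRGQRQLKASRSDKLSAVIPGIAVVKAREYGRCQDKGLGKEGSAFWWSG
CHFVDTSQTSTCDLEGEWNLWTIVVLVFDMNSEHYGLMPKRVEGTILFKPMLPHQQSYLLFWQGLGTLFK
DWMADLDQLFTGLHGPSVNP
>rscJ|structural-conserved synthetic stand-in sequence
MIRWDLNALNPQLPFSDSSRENRISVSRWLFMDSAVCDLSTYGRCQRVKKAKWYLQHETIREVRRSEPGA
VLRAQLEGTDTSAEETCGITLMRASKEVGIFQEVLLDAVVSGKNSIELALVGSMKTTETTFDVGRTNVAF
TVGPAILGRGLIDEMHMYIEPPTFVRAIDHAASSGGGGRE
>rscN|structural-conserved synthetic stand-in sequence
MKRKQSGRWFPTCVPILAAFKPQVASNYIKGIVSLEGQFFGAPAVKKESNGIKDLPMVGIGREISEIIKQ
ARKLSATYQKVRFLMLLDSVAESRMGSPMFGGEDGDDIPGSINGISKVPSDNVGTANLSKFMLAGSEDED
GMVPAAMTVSTYEFPLRKFRITYCTIGLLRGVNIVGGLDAPIIAILPAYFVLNQAYKIKDSITGRTESWM
SVAGNGKTRGFGFRPQDGSEPIEANFKSLREYFKAIEVDPVGSIQVAAHSIFLFTGLMLNSVVSVGISSI
VVAVSVPMFY
>rscQAB|structural-conserved synthetic stand-in sequence
MAGAALNRALQKINELSWVLCKKRLDKASGEVVNSLIGNDSLCSRNADDAYKFLYAVFKGTDESERAKFS
TAFTGMLKIETDLSPEHHYKSIWHPRMGTLVRKRAAKKLGHRTWNRQIFDTYYSFQLIMAHEGDRLAELR
RAIYNNPANVLANINFLTLRRAELGRWRPGMVQRLGSEFKSSYVLLEVLAPDKTLTNDNAPEAVLKIVDF
FSIITIESAAVTTAIWRTKFQVFDIFFLVLDMPWSITSAIYRHLCVTRDA
>rscR|structural-conserved synthetic stand-in sequence
MSTSLTFKGKAIPWELSQVFRKVNRNFIEVVNVPTNLKSGETAGRMKPLLEAEESMKTHPKTLHASLTNQ
TAEDDNPQQHALQILKHPLGSESTNATLAPIGVVNGSAITHATRELYEMVEEPFMLNRYNIDEGGGSQSL
CPKMPNRYQARDNLIYWAQGHSPASPYHAGVSVKEEELAYSPMASKGCGDSLKSARLFVA
>rscS|structural-conserved synthetic stand-in sequence
MVAVGGTLLAKREMNAGLEFQGLIGAAMVDGSVVALIPRPTYPAVDKVFKVMHDKVWLIESEGPDPPNSP
PHLDAARMPAREVRHGPRGKDGELKVQCENLSWIIAHGGFGRVDFQAENDVIASPVMHSDWETIKRNVHT
IGPVNCHKDP
>rscT|structural-conserved synthetic stand-in sequence
MDFVQDITPVDLVVMPLGRRLYQDVELETQCVSGGHTSEQGRWDISPTVDEITRTQRENEFVAVEMTKSS
RFRYRPRLLSFQIRQYETSIPFSSKQTVFLIALAFDDILVIKILAGGVCWERIGDAQAESDIEELDISYG
QDFKPEGVVVCAIFITSDLYEVCITMQPQIPGFDYAIVIVKPGCILPHWLLVEHHDGTEY
>rscU|structural-conserved synthetic stand-in sequence
MAAGFLEGEGLWLRYDIRKLANSASRGVMCVRQKTTPGLPKKKMGGKGRGRPWLEFLRETPLNLFEKQRK
LWIEHVEVIFNPLHAHDLVNLMGGAEEYWSIWRGIFFPFLTRKDGGLMSEEMEGVDVDPFNDKPPAAVEY
SKTLKFLLDLVEAVSDIKLIEAYGQMRKLPTEYLSPPACSTYLGMCAAGIKEQARYRERGLSVEASFINL
VCKWRGNKNRVHTTIENSISEASNGKNRLD
>rscV|structural-conserved synthetic stand-in sequence
MNKALDPRDLSEDRNGVAIPYPSNNESAPLDKQVDYLACPKSRSARTIHDIGPKRYAYSVGSGDDAAQAP
LDADPTEFTETDSDSGRLKVSTLEEKYHQCAEGYMWFNQFEMSEENEGQPQLEFVTNFIAVPWDLEKIEA
DLKWVYTAKETWYELKMGEYKHASRQIVYPLSTKLYADFLGEEIVARVINAIQWLDEKLPIYDEIAEKCV
FSDFIYKLDIEDPTVAPETWTPAACDTKQEQNGAEKQDTLVKMARALVEYIAKEFTLFSNGMEGLLAHGD
DNDEERESQYCSAVGSAAPG
>rspL|regulatory synthetic stand-in sequence
MLYIAVTSIGYTRTQLRTTLDDFTGNTPLACQYSERLLAPGFEVYSTSRFINTAINLQQIADLIKIEHQL
SPFGKDPYLNPAELVASAYGISGLPRFFRHAEMHLCKTSLLLKRYEPQITTFKKDMKEWELNVAEAHEGI
MVIVQISSKGSVAGLRETKLRPADLLAREE
>rspR|regulatory synthetic stand-in sequence
MKPNESHGGAILGPRTLLLDPDMCNLLSPELALNAKWRRQSRGPHHYLDEPSAMTADQLDSMEDRKAGAH
QSEPPWKYIRRYSRKHVRVEMDAYLAILWLPEKSFGFHDDNLYCEAMCVIAISRQTILDEYIVDAATRYV
TPMPKGNSASIPVILLPWRKPGGKGVTWKRVIVARLSHTRMDRQLGANQLFDGVDAFRAGSSRKAVGGSK
>rspA|structural-nonconserved synthetic stand-in sequence
MAASLVLCIKSVCDMADGRKVLSVNSGQMGLDVVMLAHIRNLTSKNDDLLVEGGETHGSEAAIIIYRQID
TLGGDGAALGAVTNDDVKPLPAGIDFREQVPYALPEKNNGYDTEDRICELKIYLSLSINYTKKTKAIIKD
QDVDYARDVAAKQKRVQPSGALAYKKDDFDLPKGQEDEKAAYERSLSTDK
>rspB|structural-nonconserved synthetic stand-in sequence
MYGDREKQMQVQPKSERLFGFIKEFPWASQGPYMRKYGLYVRNNSNPRSRTIYWSDHAVRLGNFKDQLDL
SYIVLIPKGLLMLLLNFINLATKVAFVLQQLIMNVHTEEHFGLYLHANETGPSVLPERAVETTMASDQEK
QSVYMGPDCDNGPSYALRDN
>ropE|effector synthetic stand-in sequence
MNKALNATKIEAQDRPSGSPVVGHVYQIVKARRERPNLAGLLPLKVGARVHLALRGLLNGTQFTRIPFEM
VANKSIQIEEGKLIMVSDYLQPLAPKLLNLQGLTVVLRIQLFYESTRTGVPVKTPEISMRLRPVIDGKMG
GGKRGLGADTPYYFVPRSFGVAPMEPEKQDDWVEDSSPLEMTQSDVTGQLFSIDGSKMKQKPMRGIAYMS
YEINTNLRLEHQMYPVRSRERIAKGVSVDAAMWDNMTRFGAYYESHEVHDPSNTVVSWEGIIVKYVEQAR
NLLGGANSFGVESLLLLASS
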